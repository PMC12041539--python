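# Methods

## Graph construction and featurisation

Molecules are modelled as undirected heavy-atom graphs (implicit
hydrogens, the convention for SMILES benchmarks); every bond is stored as
two directed entries with identical features. The 56-d atom vector is laid
out as: formal-charge one-hot over {−3..+3} (7 slots), degree one-hot over
{0..10, ≥11} (12), hybridization one-hot over {sp, sp2, sp3, sp3d, sp3d2,
other} (6), ring flag (1), aromatic flag (1), three affinely scaled
scalars — atomic mass (m − 10.812)/116.092, van der Waals radius
(r − 1.5)/0.6, covalent radius (r − 0.64)/0.76 — and a 26-element one-hot
over a fixed drug-like element list (B, C, N, O, F, Na, Mg, Al, Si, P, S,
Cl, K, Ca, Cr, Mn, Fe, Co, Ni, Cu, Zn, As, Se, Br, Sn, I). Unsupported
elements raise an error naming the element. The 9-d bond vector is a
bond-order one-hot over {single, double, triple, aromatic}, a conjugation
flag, and a stereo one-hot over {none, any, E, Z} (cis/trans labels map to
Z/E).

Formal charge follows the chemical convention V − N − B/2 (valence minus
non-bonding minus half the bonding electrons), clamped to [−3, 3]; an odd
bonding-electron count is rejected as malformed. In the SMILES pathway the
parser's formal charge and hybridization labels are used directly; the
hybrid-orbital counting rule H = ½(V + M − C + A) with the orbital-count →
class table (2→sp … 6→sp3d2, else other) is exposed as a standalone
operation and serves as the fallback when the parser reports no
hybridization.

Bond features are computed and stored on every graph but are not consumed
by either convolution branch (neither the spectral nor the isomorphic
update uses edge attributes); they are available for edge-aware variants.

## Spectral backbone

The encoder stacks three Chebyshev spectral convolutions
X′ = Σ_{k=1..3} Z^k Θ^k + b with Z¹ = X, Z² = L̂X, Z³ = 2L̂Z² − Z¹, each
followed by ReLU, mapping 56 → 128 → 256 → 512. "Symmetric
normalisation" is realised by running the recursion on the
symmetric-normalised Laplacian L_sym = I − D^{−1/2}AD^{−1/2} inside the
rescaling L̂ = 2L/λ_max − I (the combinatorial L = D − A remains a config
option, `laplacian="comb"`); no additional feature-space normalisation is
applied. λ_max is found per graph by power iteration (tolerance 1e−6, cap
200 iterations, deterministic start vector); `lambda_max=2.0` fixes the
exact upper bound for L_sym instead. Degree-0 nodes receive a zero
off-diagonal row in L_sym (no division error). Biases are included per
layer. All arithmetic is float64; the recursion is oracle-checked against
the explicit polynomial T₀ = I, T₁ = L̂, T₂ = 2L̂² − I at tolerance 1e−5.

The decoder is parameter-free: edge probabilities are sigmoid(z zᵀ),
symmetric by construction. The numpy pathway clamps the output to the open
interval at machine epsilon so the probability contract survives float64
rounding. All trainable pre-training weights therefore live in the
encoder (~400 k parameters).

## Contrastive pre-training

For each graph, σ² is the population variance of all entries of z; unit
directions k₁, k₂ are standard-normal draws normalised to length 1, and
z_i = z + ε_i k_i with ε_i ~ N(0, σ²). A constant embedding (σ = 0) is
left unperturbed. The composite objective is reconstruction + 0.4 ×
information. The reconstruction term is mean binary cross-entropy over the
graph's true (undirected) edges and an equal number of negatively sampled
absent pairs (fewer when the graph has fewer non-edges than edges; graphs
with no positive edge or no absent pair — single atoms, two-atom and other
complete graphs — are skipped and counted). The information term uses
cosine similarity between the flattened true adjacency and each decoded
probability matrix, with numerical floor ε = 1e−8 in the denominator; the
expectation is taken as the batch mean. Optimisation is Adam(β₁ = 0.5,
β₂ = 0.999, lr = 2e−4), batch size 32, per-graph losses averaged per
batch. A non-finite loss aborts with the epoch and offending graph.

Two numerical choices matter. (1) During training the reconstruction BCE
is computed from the raw inner products via softplus
(−log σ(a) = softplus(−a)), which is identical in value to the
probability-space form away from the clipping floor (1e−7) but keeps
gradients alive when the sigmoid saturates; the probability-space
operation is the public surface and is what the closed-form checks (log 2
at p = 0.5) exercise. (2) Because every encoder layer ends in ReLU, z is
entrywise nonnegative, so z zᵀ ≥ 0 and every decoded probability is ≥ 0.5.
Each negative pair therefore contributes at least log 2 to the BCE: on a
3-node path the exact optimum is log2/3 ≈ 0.231, and training converges to
it. Held-out reconstruction loss consequently plateaus somewhat above
zero — what pre-training can and does achieve is pushing true-edge
probabilities toward 1 while non-edges stay near their 0.5 floor, which is
sufficient to beat the log 2 chance baseline.

Weight initialisation defaults to a variance-scaled normal
(std = √(2/fan-in)); the `init="normal"` flag switches to N(0, 1) with zero
biases, which at widths 256 → 512 produces activations large enough to
stall convergence and is therefore not the default.

## Dual-branch victim model

The spectral branch reuses the encoder architecture (weights transferred
from pre-training when a backbone is supplied; everything stays
trainable). The isomorphic branch applies three GIN-style layers with
injective sum aggregation, h′_v = ReLU(BN(W[(1+ε)h_v + Σ_{u∈N(v)} h_u])),
ε fixed at 0 (a flag makes it learnable), and a single affine link
function per layer — a two-layer perceptron per link would push the model
past the 1 M parameter budget. After every layer the two branch outputs
are summed and the fused tensor feeds both next layers; the final fusion
is the stated "+" aggregation. Graph readout is a mean pool, followed by a
512 → 256 affine + batch-norm + ReLU head and a 256 → k affine output,
sigmoid-activated for classification and identity for regression. With
k = 12 tasks the model has 822,529 trainable parameters.

Batch normalisation in the isomorphic branch normalises over the current
graph's node set in both training and evaluation (no running statistics):
per-graph node statistics vary too strongly across molecules for a
meaningful running average, and per-graph normalisation keeps predictions
independent of batch composition and invariant to node relabelling. The
head batch norm operates across the batch of graph embeddings with
conventional running statistics for evaluation.

Training uses masked losses — missing labels (NaN) contribute to neither
numerator nor denominator — with Adam(β₁ = 0.9, lr = 2e−4), seeded 80/10/10
style splitting: a seeded validation fraction (default 0.1) is held out and
the epoch with the lowest validation loss supplies the final weights, up to
the epoch cap. Scaffold splitting is out of scope.

## Adversarial attack

The scheduler draws θ ~ U[0, π] once per inference batch (per-sample
granularity by config) and fires when sin θ ≥ 0.5; the long-run frequency
is exactly 2/3. The attack re-runs the latent perturbation procedure at
inference with its own seeded generator (pre-training draws are not
persisted), forms A = z zᵀ, A₁ = z₁z₁ᵀ, A₂ = z₂z₂ᵀ (self-products — they
keep each reconstruction symmetric), evaluates the pre-training loss on
them against the true adjacency, and differentiates with respect to each
matrix. The combined gradient is symmetrised; μ_g is its mean over
existing-edge entries (`mean_over="all_entries"` gives the literal
all-entries mean). An edge is dropped when μ_g is strictly greater than
its gradient — the rule as printed, which removes the low-sensitivity
edges; a config flag inverts the comparison for ablations. No drop-budget
cap is imposed; the per-sample log records each decision and drop count.
Dropping edges keeps the adjacency symmetric and 0/1-valued and can only
shrink the edge set, so the attacked graph is always a valid subgraph with
unchanged node features.

## Synthetic data and fixtures

The fixture module embeds 228 deterministic drug-like SMILES: ten common
drugs, charged species, E/Z stereo pairs, substituted aromatic and
saturated ring scaffolds, and homologous acyclic series — all verified
parseable, covering every feature block. The synthetic classification
task samples fixtures with equal probability from the ring and no-ring
pools (guaranteeing 40–60 % balance), optionally prepends a small
substituent when the decorated SMILES remains valid and keeps its class,
and labels each molecule by ring presence. The label is a deterministic
function of the graph that is literally visible to the featurisation (the
ring flag is an atom feature), so end-to-end learnability cannot fail for
statistical reasons. What the synthetic task does *not* emulate: label
noise, activity cliffs, scaffold-level distribution shift, class
imbalance, or the weak structure–label correlations of real assay data —
passing it demonstrates that the pipeline can extract a structurally
encoded signal, not that benchmark-level AUCs transfer.

## Problem sizes and defaults

Desk-scale runs use: contrastive pre-training on 200 fixture molecules for
30 epochs (the remaining 28 fixtures are the held-out reconstruction
split); the ring-label task at n = 500 with a 400/100 train/test split and
20 training epochs, which comfortably reaches held-out AUC ≥ 0.9; attack
evaluation averaged over 5 seeded runs. Full ZINC/MoleculeNet runs use the
same code paths with larger inputs and epoch caps (up to 1000 epochs with
validation-based selection).

## Known limitations

- The NumPy autodiff core is single-threaded per operation and materialises
  dense n×n matrices; it is sized for molecules (tens of atoms), not for
  large graphs.
- ReLU-nonnegative embeddings bound decoded probabilities below by 0.5
  (discussed above), so reconstruction losses have an architecture-level
  floor.
- The attack's damage on the synthetic task is modest: the ring label
  remains partially readable from untouched node features, so AUC drops are
  qualitative (attacked < clean) rather than the large drops achievable on
  assay tasks where structure carries most of the signal.
- Edge features are computed and serialised but unused by the default
  convolutions.
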