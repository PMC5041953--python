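# Methods

## Model overview

The package computes three layered quantities:

1. **Disease semantic similarity (SS)** on a rooted disease DAG, an
   edge-based measure built from information-content (IC) distances.
2. **lncRNA functional similarity (FS)**, a best-match-average comparison of
   the disease groups associated with two lncRNAs.
3. **Association scores** for every lncRNA–disease pair, from a
   Laplacian-regularized least-squares (LapRLS) solver over integrated
   similarity matrices — a companion re-implementation of the LRLSLDA
   scheme in its standard published form, included so the similarity
   measures can be exercised and evaluated end to end.

The underlying assumption throughout is that functionally similar lncRNAs
associate with semantically similar diseases, and vice versa.

## Disease DAG and information content

The hierarchy comes from MeSH Category C descriptors (tree-number nesting
defines parent/child edges; descriptors appearing in several branches get
several parents) or from an explicit edge list. A single virtual root with
IC 0 is inserted whenever the input has multiple top-level terms; when an
edge list has a unique parentless node, that node is the root itself.

`IC(t) = −log p(t)` in **nats**. The log base is part of the model: γ enters
the similarity through `1/(1+γ)` un-normalized, so changing the base changes
SS, not just its scale. Two estimators of `p` are provided:

* **structural** (default): `p(t)` = inclusive descendant count of `t`
  divided by the number of terms (virtual root excluded), `p(root) = 1`.
  Self-contained — no annotation corpus required — and monotone by
  construction (descendant sets nest along edges).
* **annotation**: add-one smoothed fraction of associations annotated at or
  below `t`. Offered because corpus-frequency IC is the classical
  alternative; which estimator the original model used is not recoverable,
  and neither is claimed to reproduce it bit for bit.

IC monotonicity (`IC(child) ≥ IC(parent)`) is what guarantees α, β, γ ≥ 0.

## Semantic similarity

For terms *a*, *b* with `DIST_IC(x, y) = |IC(x) − IC(y)|`:

* **MICA** — common ancestor (query terms included) with maximal IC. The
  inclusive convention makes the MICA of an ancestor/descendant pair the
  ancestor and lets `SS(leaf, leaf) = 1` emerge from the formula. Reading
  "most informative" as maximal IC keeps the identity
  `α = DIST_IC(root, MICA) = −log p(MICA)` internally consistent.
* **MIL(x)** — leaf descendant of *x* with maximal IC; a leaf is its own MIL.
* `α = IC(MICA)`; `β` = mean IC-distance of each term to its MIL (the
  *generality* of the queries); `γ` = summed IC-distance of both terms to
  the MICA. γ is measured in IC distance by default; a shortest-path
  edge-count variant (`gamma_metric="edges"`) exists for sensitivity
  analysis only.
* `SS = α/(α+β) · 1/(1+γ)`, with `SS ≔ 0` whenever `α = 0` — this covers
  both the meets-only-at-root case and the degenerate `α = β = 0` case
  (0/0) in a way consistent with "no shared biology".

Ties in MICA/MIL selection are broken by lexicographically smallest term id.
Tied candidates share the same IC, so SS is unaffected; the tie-break only
makes the *reported* component nodes deterministic across platforms.
Leaf/root checks are structural (out-degree, identity), never IC-equality
comparisons.

The diagonal of the SS matrix follows the same formula: 1 for leaves,
`α/(α+β) < 1` for internal terms — an internal disease compared with itself
is penalized for generality.

## Functional similarity

`FS(i,j) = (S_{i→j} + S_{j→i}) / (|G(i)| + |G(j)|)` with
`S_{i→j} = Σ_{d∈G(i)} max_{d′∈G(j)} SS(d, d′)`. Each best-match term is in
[0, 1], so FS is bounded and symmetric by construction. The FS diagonal is
**not** forced to 1 (it equals the mean self-similarity of the group's
diseases); `unit_diagonal=True` overwrites it for downstream consumers that
expect unit diagonals — which convention the original model used is unknown,
so both are available. Empty disease groups are a hard error in the library;
the prediction pipeline downgrades them to an all-zero similarity row,
because cross-validation folds can legitimately empty a group.

## Predictor (companion re-implementation)

* **Gaussian interaction-profile kernel**:
  `K(u,v) = exp(−γ‖y_u − y_v‖²)`, `γ = γ′ / mean(‖y‖²)` with the mean over
  entities having non-empty profiles. All-zero profiles keep `K(u,u)=1` and
  do not dilute the bandwidth.
* **Integration**: entrywise mean of the semantic/functional matrix with the
  corresponding kernel; entries with no semantic value fall back to the
  kernel alone. When a precomputed lncRNA expression-similarity matrix is
  supplied it enters an equal-weight average (how the original combination
  weighted its three lncRNA sources is not published; equal weights are the
  neutral choice).
* **LapRLS**: normalized Laplacian `L = I − D^(−1/2) S D^(−1/2)` (zero-degree
  rows fall back to identity rows), closed form `F = S (S + η L S)⁺ Y` via
  Moore–Penrose pseudo-inverse (rank-deficient FS matrices are routine, and
  a warning is emitted when the system is singular), disease space solved as
  the transpose, blended `F* = w·F_l + (1−w)·F_d`.
* **Defaults**: `γ′ = 1` (both spaces), `η = 1` (both spaces), `w = 0.5` —
  neutral values; no published parameter table exists to copy, and all are
  exposed on `PredictorConfig`.

## Cross-validation

* **Global LOOCV**: each known association is removed in turn and every
  Y-dependent quantity — disease groups, FS, both kernels, scores — is
  rebuilt without it, so the held-out pair never leaks into training. The
  held-out score is ranked against all never-known pairs pooled across all
  diseases; per-fold Mann–Whitney fractions (ties at half credit) average
  into the global AUC, and the ROC polyline is the step curve of normalized
  held-out ranks.
* **Repeated k-fold**: known associations are partitioned at random, each
  fold held out once, one AUC per fold against the never-known candidate
  set (other folds' test pairs are excluded from training but not counted as
  candidates). Repetition *r* of seed *s* draws from the numpy seed sequence
  `[s, r]`, so any repetition is reproducible in isolation.
* **AUC** is computed from midranks (scipy `rankdata`), algebraically the
  Mann–Whitney statistic normalized by `n⁺·n⁻`; ROC points come from
  scikit-learn's `roc_curve`.
* Top-k candidate lists exclude known partners and break score ties
  lexicographically so output is deterministic.

## Synthetic benchmark

The generator emulates the *shape* of a disease vocabulary and a curated
association table, not the marginal statistics of any real database release.

* **DAG**: a tree grown under a depth cap (default 40 terms, depth ≤ 5,
  mean branching 2.5), with a 10% chance per term of a second parent drawn
  from non-descendants. These defaults give the mix of shallow/deep and
  single/multi-parent terms the similarity components need to be exercised.
* **Associations**: 24 lncRNAs in 3 modules; each module's 5 diseases are
  sampled under a shared internal ancestor, so the planted signal is visible
  to the *semantic* similarity rather than to co-annotation alone.
  Within-module pairs associate with probability 0.6, any pair with noise
  probability 0.05, and every lncRNA keeps at least one association. At
  these settings a table has ~80 associations (3–4 per lncRNA), enough for
  LOOCV to be informative while a 10-seed sweep stays around a minute.

What passing on this benchmark does **not** show: robustness to the
long-tailed degree distributions, annotation bias, and synonym noise of
real curated tables, nor anything about the absolute AUC reachable on real
MNDR/Lnc2Cancer snapshots (those depend on database versions, the
disease-name mapping, and predictor tuning that are not reproducible here).

## Known behavior of the leak-free LOOCV null

With shuffled (label-permuted) associations the pooled LOOCV AUC falls
systematically **below** 0.5 (≈0.37 at the default benchmark scale, ≈0.43 at
2–4× larger and sparser scales) rather than sitting at chance. This is a
property of strict per-fold recomputation, not a defect: deleting the
held-out pair removes entry *j* from lncRNA *i*'s interaction profile, which
lowers the kernel similarity between *i* and exactly those lncRNAs
associated with *j* (and symmetrically for disease *j*), while *raising* its
similarity to entities that could not help recover the pair. Under a null
with no compensating semantic signal, the held-out score is therefore
stochastically dominated by the candidate scores. The effect reverses into
an optimistic bias (≈+0.1) if the kernels are computed once from the full
matrix — the information leak common in this literature. We keep the
leak-free default and document the pessimistic null instead of hiding it,
since the planted-signal comparison (planted vs shuffled AUC gap) remains
valid and is what the evaluation relies on.

## Limitations

* Disease-name resolution is exact (case-insensitive id or name match);
  synonym and cross-vocabulary mapping are out of scope, and unmatched
  records are reported rather than guessed.
* Structural IC depends on the provided DAG's extent: computing SS on the
  full MeSH Category C graph versus the subgraph of annotated diseases gives
  different `p(t)`. The default uses the full provided DAG.
* The predictor is a faithful standard-form LapRLS, not a re-tuning of the
  original; published AUC figures for specific database snapshots are not
  comparable targets.
* Dense matrix algebra throughout: fine for hundreds of terms/lncRNAs,
  not intended for whole-vocabulary (~5000-term) similarity matrices in one
  call, though nothing prevents it beyond run time and memory.
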