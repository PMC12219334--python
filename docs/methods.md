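# Methods

## The problem and the approach

A fold-switching protein adopts two distinct, functionally different folds
from one sequence.  Structure predictors trained on evolutionary signal
reliably return the *dominant* conformation from a deep MSA; the
*alternative* conformation is rarely sampled from full alignments.  The
workflow implemented here exploits random shallow subsampling: by feeding
the predictor MSAs with only a handful of sequences — sparse enough that
robust coevolutionary inference is impossible — the network falls back on
learned structural associations and sometimes produces the alternative
fold.  The package covers scheduling and subsampling, evaluation against
two references, reference-free (blind) detection by structural clustering,
and contact/coevolution cross-checks.  The neural predictor itself is
external: any object implementing `invoke(msa, job)` can stand behind the
plan runner, and a deterministic mock backend plus a synthetic-ensemble
generator make the whole pipeline testable without GPU inference.

## Sampling schedule

A depth `x:y` means `x` sequences drawn as cluster centers plus `y` extra
sequences per recycle (the predictor's max-seq / max-extra-seq knobs).  The
default schedule is one deep depth (512:5120) plus seven shallow depths
(1:2, 2:4, 4:8, 8:16, 16:32, 32:64, 64:128; every shallow depth satisfies
y = 2x), each run with 5 network models and 5 random seeds: 8 × 5 × 5 =
200 predictions per protein.  Single-sequence mode (query only) is a
distinct `SINGLE` sentinel rather than a 0:0 depth so depth invariants stay
clean.  Subsampling is uniform without replacement over the non-query rows,
the query is always retained, and each job's random stream is derived by
hashing (base seed, depth, model, seed), so jobs are independent and
reorderable.  When a real predictor backend is attached the depth pair is
passed through untouched and the backend does its own internal sampling.

## Structural scores

**TM-score.**  Residue correspondence is positional (identical sequences
within a run), so no alignment search is performed.  The normalisation
distance is `d0(L) = 1.24·(L−15)^{1/3} − 1.8` Å with the conventional 0.5 Å
floor (the raw formula is exposed separately; it is positive but below the
floor for 19 ≤ L ≤ 21 and non-positive below that).  Maximisation follows
the standard iterative scheme: superpositions are seeded from sliding
fragments of lengths L, L/2 and L/4 (minimum 4), then repeatedly
re-superposed on the residues within a distance cutoff (max(d0, 1.5) Å,
grown by 0.5 Å until at least 4 residues qualify) until the retained set is
stable; the best score over all seeds and iterations is reported.  With a
fold-switching region, the default scores and superposes on the region
only and normalises by region length (`superpose_scope="region"`); a
global-superposition variant is available, since scoring a region under
the best whole-chain transform answers a different question (is the region
in place?) than region-local superposition (is the region's fold right?).

**lDDT** is the superposition-free CA variant: reference CA pairs within
15 Å and sequence separation ≥ 2 are checked for distance preservation at
0.5/1/2/4 Å, averaged over thresholds.

**Contacts.**  Residues are in contact when any heavy-atom pair sits
within 8 Å; minimum sequence separation defaults to 1 for structural maps
and to 6 for the coevolution overlay, where near-diagonal couplings are
uninformative.  Interchain contacts of an assembly are reported in
chain-1 numbering so they can be intersected with intrachain maps.

**Secondary structure** follows the Kabsch–Sander scheme: amide H placed
1 Å from N anti-parallel to the preceding carbonyl, hydrogen bond when the
electrostatic energy 0.084·(1/rON + 1/rCH − 1/rOH − 1/rCN)·332 < −0.5
kcal/mol; helices from two consecutive i→i+n turns for n = 3, 4, 5 (the
8-state G/H/I classes, all collapsed to H), strands from parallel or
antiparallel bridge ladders (E), everything else coil.  Missing backbone
atoms demote a residue to coil with a warning; a missing carbonyl O is
reconstructed from the peptide-plane geometry.  This 3-state assigner
tracks a reference DSSP implementation within a few percent of H+E content
on noisy helices, which is all the unfolded-model filter needs.

## Default-mode evaluation

Every prediction is scored against both references, globally and over the
fold-switching region.  The success criterion is dual-fold: some row must
reach TM ≥ 0.6 to reference 1 while scoring higher to reference 1 than to
reference 2, and some row must do the converse.  Qualification requires
both clauses per row; among qualifying rows the best score per reference
is reported.  Region scores drive the verdict by default (they
discriminate fold switchers better than whole-chain scores, which dilute
the switching region with the invariant scaffold); global scores are
reported alongside and can be selected.  The threshold is configurable
downward per protein for targets with disordered-region variability.  The
dominant conformation is assigned by majority vote over deep-depth rows,
with an explicit override for cases where memorisation is known to beat
coevolutionary inference.  The folding-energy difference is plain
arithmetic, ΔE = E_dominant − E_alternative, on externally computed
(e.g. Rosetta) energies.

## Blind mode

Without references, alternative conformations are found by clustering the
ensemble:

1. **Unfolded filter.**  Per member, s = fraction of residues assigned H
   or E; members with s < Q1 − 1.5·IQR of the ensemble's s-distribution
   are removed.  A zero-IQR (homogeneous) ensemble removes nothing.  A cap
   prevents removing more than half the ensemble; note that because the
   fence is anchored at Q1, at most ~25 % of members can ever fall below
   it, so the cap is a pure safeguard.
2. **Similarity.**  S(i,j) = ½·TM(i,j) + ½·lDDT_sym(i,j), computed with a
   batched implementation of the same TM refinement (reduced seed set:
   full chain, halves, quarters — sufficient for same-sequence ensemble
   members and orders of magnitude faster than scalar scoring; agreement
   with the scalar path is asserted in tests).  lDDT is symmetrised over
   the two reference choices.  An external-scorer hook accepts a true
   structural-bitscore backend, rescaled to [0, 1]; the internal composite
   is the default because the sequence-alignment term of such bitscores is
   constant when all members share one sequence.
3. **PCA** on the rows of S, centred; the smallest component count
   reaching 90 % explained variance is kept, floored at 2.  Component
   signs are fixed by making each component's largest-magnitude loading
   positive, so the embedding is deterministic.  Near-zero total variance
   (members identical up to jitter) short-circuits to the floor.
4. **HDBSCAN** with min_cluster_size = max(5, n/20); if everything lands
   in noise the ensemble is folded back into one cluster with a warning.
5. **K-medoids (PAM)** per cluster, k = 3 (capped at cluster size), with
   deterministic initialisation: seeds at the 0/50/100 % quantiles of the
   total-within-cluster-distance ordering, ties resolved to the lowest
   member index, then greedy swaps to convergence.  Representatives carry
   their mean per-residue confidence, because correct alternative
   conformations are often predicted with low confidence and the final
   call is left to the user.

## Contact classes and quality checks

The dominant and alternative conformations' contact maps are partitioned
into common, dominant-unique and alternative-unique classes; counts are
normalised by their total so proteins of different sizes compare evenly.
An externally computed coupling matrix (MSA-transformer-style) can be
overlaid: the strongest 2L couplings (the conventional contact-prediction
budget; configurable) with separation ≥ 6 are summed per class and
reported as shares of the three-class total.  The interchain-misassignment
check discards a predicted alternative conformation when a close homolog
(identity ≥ 0.70) forms an oligomer whose interface contacts overlap the
alternative-unique contacts by more than a threshold fraction (default
0.25 of the alternative-unique set; 0 gives strict any-overlap) — such
predictions plausibly misassign interchain contacts as intrachain.

## Synthetic fixtures

Backbones (N, CA, C, O) are built by sequential internal-coordinate
placement with ideal bond geometry (N–CA 1.458, CA–C 1.525, C–N 1.329 Å,
trans ω) and canonical dihedrals: helix −57/−47, strand −139/135.  The
β-hairpin uses a 4-residue turn whose dihedrals were chosen once so the
flanking ideal strands pair antiparallel with genuine Kabsch–Sander
H-bonds; the helix-hairpin packs two helices antiparallel at ~10 Å via a
4-residue reversal loop; the helix-loop-helix variant inserts
polyproline-II flanks around that hinge (12-residue loop).  Coil decoys
are self-avoiding random-dihedral chains — drastically unfolded rather
than merely noisy, so the composition filter has unambiguous ground
truth.

Two noise models are provided.  `perturb` adds iid Gaussian displacement
per atom (sd per coordinate; RMSD ≈ sd·√3) and is the right tool for
testing metric sensitivity.  Ensembles, however, use `perturb_smooth`:
a Gaussian displacement field over residue index, smoothed with a
4-residue kernel, rescaled to the requested per-coordinate sd, and applied
rigidly per residue.  Predicted ensembles vary by collective motions with
near-ideal local geometry; iid noise at the same global magnitude shreds
backbone hydrogen bonds long before reaching comparable global deviation
(at sd 1 Å an iid-perturbed helix loses half of its assigned secondary
structure), which no real predictor output exhibits and which would make
secondary-structure-based filtering meaningless.

The default two-state ensemble is 200 members at length 60: dominant state
A a straight helix, alternative state B a helix-loop-helix, 10 % coil
decoys, noise sd 0.3–1.0 Å.  The two folds were chosen with distinct
secondary-structure content (~0.96 vs ~0.75 H+E fraction) as well as low
mutual TM-score (~0.45): the content gap makes the ensemble's s-distribution
bimodal, which is what lets a quartile-anchored outlier fence separate
decoys (s ≈ 0) from folded members without clipping the lower folded mode —
with two folds of identical content the fence sits just below a single
tight mode and inevitably flags a fraction of a percent of folded members.
Deep-depth provenance is assigned to state-A members first (full-depth
sampling yields the dominant conformation); state-B members are pinned to
the configured alternative depth; folded members get confidence 82–95,
decoys 20–45.

What the fixtures do **not** emulate: side chains, sequence-dependent
geometry, realistic Ramachandran scatter, correlated confidence/accuracy
relationships, partial unfolding, or any dependence of prediction outcome
on actual MSA content (the mock backend draws outcomes from seeded
probabilities, not from the alignment).  Passing tests therefore
demonstrate the correctness of the scheduling, scoring, filtering and
clustering machinery under controlled conditions — not predictor accuracy
on real proteins.

## Numerical choices and problem sizes

Batched pairwise TM/lDDT matrices make a 200-member all-vs-all similarity
computation take seconds on one core; converged pairs drop out of the
refinement iterations.  Acceptance-style checks run the blind pipeline on
20 seeded 200-member ensembles and the default-mode evaluation on
200-prediction mock runs at chain length 60 — large enough for stable
clustering statistics while keeping a full test cycle within minutes.
Ties are broken deterministically throughout (altloc → highest occupancy
then 'A'; dominant-vote tie → reference 1 with a warning; K-medoids →
lowest index).  Degenerate inputs (ensembles smaller than 4, all-noise
clusterings, zero-IQR distributions, empty alternative-unique contact
sets) degrade with warnings rather than errors wherever a sensible
fallback exists.

## Limitations

- The real predictor adapter is out of scope; results on real proteins
  depend on the attached backend.
- The 3-state secondary-structure assigner omits full 8-state fidelity
  (π/3₁₀ helices collapse into H; isolated bridges into E).
- Blind-mode PCA treats similarity-matrix rows as feature vectors; a
  kernel decomposition of S is a reasonable alternative not implemented.
- Sequence searches (for homolog identity in the misassignment check) and
  coupling computation are external; the package consumes their outputs.
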