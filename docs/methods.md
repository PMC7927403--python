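# Methods

## The activation descriptor

GPCR activation rearranges the transmembrane bundle; for the adenosine A2A
receptor the agonist must displace Val84 in TM3 to avoid a steric clash,
while Leu249 in TM6 stays comparatively fixed. The package therefore uses
the Cα–Cα distance d(Val84, Leu249) as a scalar activation descriptor:
active-state crystal forms open it to 14.30–14.53 Å, inactive forms sit at
12.96–13.36 Å, so the two states separate by roughly 1.6 Å with the widest
opening in the adenosine-bound structure (2YDO) and the narrowest in the
antagonist-bound structure (5IU4).

Distances are Euclidean norms of author-numbered Cα coordinates and are
invariant under the rigid-body operations used everywhere else, so they can
be measured before or after superposition. Values are reported to 2
decimals (Å); computation is double precision throughout.

### PDB input conventions

`read_structure` keeps only `ATOM` records with atom name `CA` for the
requested chain, resolving alternate locations to the highest occupancy
(ties to the first record encountered). Residues outside a configurable
author-numbering window (default 1–320 for the A2AR) are dropped so that
fusion partners (BRIL, lysozyme) used to crystallise inactive-state
receptors cannot collide with receptor numbering. Insertion codes are
rejected with an error rather than silently renumbered — none occur at the
descriptor residues in the relevant entries. Malformed coordinate fields
raise with the offending line number. Multi-model files yield one model per
`MODEL`/`ENDMDL` block.

### Superposition and residue stability

Ensembles are aligned by Kabsch least squares over the intersection of
residue numbers (no sequence alignment; entries of the same receptor share
author numbering). scipy's `Rotation.align_vectors` provides the optimal
proper rotation; the post-fit RMSD is recomputed from the transformed
coordinates because the solver's internal residual loses ~1e-7 Å to
cancellation near perfect fits. Collinear (rank < 2) atom sets are
rejected: the rotation would be underdetermined. Ensemble alignment fits
every member to member 0, then refines once against the running mean
structure (2 passes by default); further passes change positions at the
1e-3 Å level and are unnecessary.

Per-residue stability is the RMSD of the aligned positions about their
ensemble centroid, `sqrt(mean ‖x_i − x̄‖²)` — zero iff all members
coincide, linear under uniform scaling of the deviations. The phrase "mean
RMSD displacement from the mean" admits two readings (mean of per-member
distances vs RMSD about the centroid); we implement the RMSD-about-centroid
reading, which is the standard second-moment quantity. On the synthetic
reference ensemble this yields ≈ 0.45–0.5 Å at Leu249, consistent with the
~0.4 Å heterogeneity reported for the real crystal forms given that the
alignment protocol (software, equivalences, weighting) behind that number
is unspecified.

## Trajectory analysis

A trajectory is reduced to one descriptor value per frame. Frame *i* is
stamped with time (i+1)·Δt; the first `anneal_ns` (default 50 ns) are
treated as relaxation and excluded from all statistics, with the frame
falling exactly on the boundary counted as annealing (strictly-greater
cut). Smoothing uses a *trailing* 20-frame moving average with partial
leading windows, so the output aligns left-anchored with the raw series
and has equal length; windows are summed independently rather than via a
running cumulative sum, which would drift above 1e-12 over thousands of
frames.

Production distributions are compared with a two-sided Mann–Whitney U test
and a two-sample Kolmogorov–Smirnov test. For groups of ≤ 8 observations
the Mann–Whitney null distribution is enumerated exactly over all
C(n₁+n₂, n₁) midrank assignments (correct under ties, p = 1 for identical
samples); larger groups use the normal approximation with continuity and
tie correction. The KS p-value is asymptotic. MD frames are autocorrelated,
so these p-values index separation rather than strict independent-sample
inference — the same convention used when such tests are applied to
pooled trajectory histograms.

`classify_state` calls a run agonist-like when the production median lies
closer to the active reference distance than to the inactive one, with a
±0.1 Å dead band around the midpoint reported as indeterminate. The dead
band is a quarter of the stationary noise scale (0.4 Å) — narrow enough
not to swallow genuine drift, wide enough to absorb median jitter.

## Docking-score screen

Scores are dimensionless, more negative = better. The agonist/antagonist
classifier is "predict agonist iff score ≤ t"; with that rule the MCC,

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

is a step function of t that changes only at observed scores, so scanning
the pooled score multiset attains the global optimum over all real
thresholds (the pooled maximum score always yields MCC = 0, which covers
the below-all-scores regime). MCC is defined as 0 when any denominator
factor vanishes. Ties on the optimum break toward the most negative
threshold — the stringent choice that avoids optimistic selection.
Shortlisting of untested candidates is deliberately *strict*
(`score < threshold`). Inactives are excluded from threshold fitting; they
are reported through their separate median. The enrichment factor ranks the
pooled actives+decoys ascending by score (ties by compound id) and divides
the active fraction in the top ⌈f·N⌉ by the overall prevalence.

## Pharmacology

All concentration-response fits are three-parameter logistics with unit
Hill slope, Y(c) = basal + (Emax − basal)/(1 + 10^(−(pEC50 + log₁₀ c))).
Replicates are averaged per concentration with uniform weights before
least-squares fitting (scipy `curve_fit`, trust-region-reflective with
bounds); pEC50 is bounded to the tested window ± 1 log, standard errors
come from the Jacobian, and non-convergence is flagged with NaN parameters
rather than raised. Proliferation fits constrain basal = 100 % and
optionally Emax to the assay's maximal-inhibition floor; span = 100 − Emax
and the proliferation factor is pIC50 × span (clamped to 0 and flagged for
negative spans).

Competition binding fits a descending unit-slope displacement curve
(top, bottom, log IC50 free) on data spanning ≥ 3 log units and converts
IC50 to Ki with Cheng–Prusoff using the tracer's KD = 65 nM and
[L] = 300 nM defaults. With IC50 = 1 µM these defaults give
Ki = 1000/(1 + 300/65) = 178.1 nM. A compound is "not fully displacing"
when the fitted lower plateau exceeds 20 % of the fitted window — the
criterion is configurable because no quantitative definition accompanies
the published observation of partial displacement.

Tracer kinetics fit B(t) = Beq(1 − e^(−kobs·t)) up to the competitor
injection time and mono-exponential decay afterwards, jointly over
(Beq, kobs, koff); kon = (kobs − koff)/[tracer] and KD = koff/kon. A fit
with kobs ≤ koff is unphysical (negative kon) and raises. Potency
correlations are Pearson r with a 95 % Fisher-z interval; incomplete pairs
are dropped and counted.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical shape* of each input at the
study's conditions, never the physics:

- **Ensembles** place 30 Cα atoms on two idealised antiparallel helices
  (rise 1.5 Å, radius 2.3 Å, 100°/turn; residues 75–89 and 242–256) with
  the helix offset solved so d(84, 249) hits the requested value exactly,
  then apply per-atom Gaussian jitter and a random rigid motion. The
  14-member reference ensemble pins each member's descriptor at the
  published value (range endpoints are published; interior values are
  interpolated placeholders, and the table is labelled synthetic).
  jitter σ = 0.25 Å/axis was chosen so the per-residue scatter
  (≈ σ·√2.5 under the pair-distance constraint, plus alignment noise)
  matches the reported ~0.4 Å Leu249 heterogeneity.
- **Trajectories** are Euler–Maruyama Ornstein–Uhlenbeck series: target =
  start distance during annealing, then the forced-state distance;
  reversion rate 0.05/ns (τ = 20 ns), noise chosen for a 0.4 Å stationary
  s.d., 0.1 ns frames, 500 ns total → 4500 production frames. Real MD has
  multi-timescale kinetics, rare transitions and correlated noise that
  this deliberately lacks; passing tests show the *analysis operators* are
  correct, not that real trajectories will separate this cleanly.
- **Scores** are Gaussians shifted post hoc so sample medians equal the
  requested values exactly (medians, not means, because medians are what
  the screen reports), at class sizes 39/38/133. The 11-compound candidate
  fixture is fabricated with 6 scores below −7.33, mirroring the published
  shortlist size; individual candidate scores were never published.
- **Assays** evaluate the exact fitted model on a log-spaced grid with
  additive Gaussian noise per replicate (no published noise model; 5 %
  of the response window is typical plate-reader scatter).

Every generator is a pure function of its spec including the seed, and
returns a truth record with the generating parameters and realised values.

## Numerical choices and degenerate inputs

- Superposition requires ≥ 3 shared residues and non-collinear coordinates.
- Template-selection ties break lexicographically on structure id.
- Exact Mann–Whitney enumeration caps at 8 per group (C(16,8) = 12 870
  assignments); beyond that the asymptotic path takes over.
- The annealing cut uses a 1e-9 relative tolerance so 50 ns / 0.1 ns
  counts exactly 500 frames despite binary floating point.
- Pipeline tables are written with `%.6g` formatting and no timestamps, so
  re-running an identical config reproduces every output byte-for-byte.

## Problem sizes

The shipped tests and the acceptance script run at the analysis's natural
desk scale: 14-member ensembles, 500 ns/0.1 ns synthetic trajectories
(5000 frames), 40 seeded classification replicates, 100 random score sets
for the scan oracle, 200 noisy curves for the pEC50 bias run, and a
16-compound potency panel at generating correlation ρ = 0.80 — the panel
size of a per-compound-per-cell-line potency comparison.

## Known limitations

- No mmCIF, no binary trajectory formats (DCD/XTC), no sequence-based
  residue equivalencing: structures must share author numbering.
- The Mann–Whitney/KS p-values on trajectory data inherit the
  autocorrelation caveat above.
- The published 95 % CI for the potency correlation (0.85–0.91) does not
  bracket its own point estimate r = 0.80 and is likely a typographical
  slip; the package reports the standard Fisher-z interval and makes no
  attempt to reproduce that printed interval.
- Dose-response SEs are Jacobian-based (no profile likelihood); for
  ill-conditioned curves (incomplete plateaus) they understate the true
  uncertainty.
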