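# Methods

This package reimplements, as a tested pipeline over synthetic data, the
computational analyses behind the finding that soluble adenylyl cyclase
(sAC) in nonmammalian sperm is controlled directly by intracellular pH
rather than by bicarbonate or calcium. It has four analysis stages —
ortholog genotyping, enzyme kinetics, the flagellar cAMP budget with a
spawning-cascade model, and sperm-motility scoring — each fed by a seeded
synthetic-data generator whose parameters are the study conditions.

## Ortholog genotyping (`sacph.orthosite`)

Human sAC coordinates bicarbonate through two positively charged residues,
K95 and R176. An ortholog's "genotype" is the pair of residues at the
positions homologous to these two, written `X/Y` (e.g. `K/N` for sea
urchin, `N/R` for salmon, `K/R` for mammals), with a charge class counting
how many of the two are positive (K, R or H).

Queries are aligned to the reference by global pairwise alignment with
affine gaps (Needleman–Wunsch–Gotoh through `Bio.Align.PairwiseAligner`),
BLOSUM62, gap open −11 / extend −1 (a gap of length L costs
`open + (L−1)·extend`). `X` is treated as fully unknown: it scores 0
against every residue and never counts as an identity. Reference positions
are mapped through the alignment (1-based, inclusive, truncated-isoform
numbering throughout); a reference position opposite a gap maps to
"absent" and contributes `-` to the genotype label (counted non-positive).
Two catalytic-loop motifs, AGD (97–99) and FDKG (338–341), are checked as
conservation controls. Percent identity defaults to identities over
aligned columns excluding terminal gap runs; the denominator policy is
switchable because published identity figures rarely state theirs.

The packaged reference is a **synthetic** 469-residue sequence with the
documented functional-site architecture planted at the human coordinates
(`sacph.reference`); the real protein is not redistributed. A deterministic
synthetic sea-urchin-like ortholog (`synth.gen_urchin_like`) carries a
22-residue N-terminal extension and a 92-residue linker so that every
reference site maps at the coordinates documented for the real enzyme
(95→117, 176→198, loops 119–121 and 418–421). Multiple-sequence alignment,
homology search and tree inference are out of scope: curated sequences and
newick trees are inputs.

## Enzyme kinetics and statistics (`sacph.kinetics`)

Assay readings are converted to cAMP through a 4-parameter-logistic (4PL)
standard curve fitted by least squares (initialised from the data range
and the geometric-mean calibrator concentration); readings outside the
monotone range are flagged rather than inverted. Activity is
pmol cAMP·min⁻¹; the turnover number is
`k = camp_pmol / time_s / enzyme_pmol` (mol cAMP · mol sAC⁻¹ · s⁻¹).
Reaction time defaults to 10 min; well volume and enzyme amount are
configuration, not constants.

Fold changes default to the ratio of condition means (the bar-chart
convention), with a median-of-ratios alternative. The pH-profile
descriptor reports interior local peaks and troughs and the max/min ratio,
enough to flag the biphasic shape of the purified sea-urchin enzyme
(twofold local peak at pH 7.0, trough at 7.2, roughly threefold surge at
8.0 in turnover units).

Statistics follow the study's recipe and are implemented in-package so the
exact small-sample distributions are available (scipy and statsmodels are
used as independent oracles in tests, never as the implementation):

- **Mann–Whitney U**: exact permutation p (enumeration of all label
  assignments) up to a combined n of 12, otherwise a tie-corrected normal
  approximation with continuity correction. All-tied data returns p = 1
  with a degeneracy flag.
- **Kruskal–Wallis**: tie-corrected H; exact permutation p up to a
  combined n of 8, chi-square otherwise. **Dunn's post hoc** z tests use
  the pooled tie-corrected rank variance with Benjamini–Hochberg
  adjustment (the study names Dunn's test without its correction; BH was
  chosen for consistency with the mutant panel).
- **Benjamini–Hochberg**: standard step-up, monotone and capped at 1.

The mutant panel comparison strates by (pH, metal), computes each mutant's
fold vs wild type and a Mann–Whitney p, and BH-adjusts across the whole
panel; strata without wild-type wells are skipped with a warning.

## Flagellar cAMP budget and spawning cascade (`sacph.flagellum`)

The budget arithmetic is exact: with N = 7,000 sAC copies per flagellum
and MgATP turnover rising from 0.035 s⁻¹ (pH 7.2) to 0.106 s⁻¹ (pH 8.0),
the net synthesis rate is N·Δk = 497 molecules·s⁻¹. In the 2-fL flagellar
volume one molecule is 0.830 nM exactly (1/(N_A·V)); the rounded
1-molecule ≡ 1-nM convention used in the study's prose is an explicit
opt-in flag, never the default. Occupancy of cAMP targets is a Hill form
c^n/(c^n + K^n) with PKA K_D = 10 nM (the upper end of the reported
2–10 nM) and HCN K_½ = 740 nM. With phosphodiesterase hydrolysis time
constant τ = 0.35 s, the steady state of dc/dt = s − c/τ is s·τ
(≈ 144 nM for the 497 s⁻¹ step).

The **spawning cascade** is a deterministic fixed-step model defined by
this package — the study reports the event sequence and timings, not
differential equations — with every rate constant surfaced:

- Membrane potential relaxes first-order (τ_Vm = 0.2 s) toward the K⁺
  Nernst potential `(RT/F)·ln([K⁺]o/[K⁺]i)`. External K⁺ steps at t = 0
  from 27 mM (artificial seminal fluid) to 10 mM (spawning mix) or 30 mM
  (high-K⁺ control). Internal K⁺ is not measured in the study; the default
  300 mM gives a plausible resting potential near −61 mV and is exposed in
  configuration.
- The Na⁺/H⁺ exchanger SLC9C1 is a threshold gate: open while V_m is below
  −70 mV. While open, pH_i relaxes first-order from the resting 6.84
  toward 7.2 (τ_pH = 72.13 s). An optional linear shift of the gate
  threshold with PKA occupancy models the reported cAMP feedback on SLC9C1
  voltage dependence; it is off by default.
- cAMP (in molecules) obeys dc/dt = N·k(pH_i) − c/τ with τ = 0.35 s, so
  free cAMP is quasi-steady on the pH timescale.
- Motility switches on once PKA occupancy has exceeded 0.8 continuously
  for a 10-s phosphorylation delay, and persists.

Two modelling choices deserve emphasis. First, the default spawning
scenario uses a **monotone** k(pH) anchored at the measured 7.2/8.0
turnover numbers with a low resting anchor at pH 6.84: under the
fast-hydrolysis steady state, the biphasic purified-enzyme curve (local
peak at 7.0 above the 7.2 trough) would predict free cAMP *falling* from
rest to the post-spawn state, contradicting the observed whole-cell cAMP
rise; the study measures total cAMP accumulation and does not reconcile
the two, so the package keeps the biphasic curve available separately and
uses the monotone form for the cascade. Second, defaults are tuned so the
cAMP half-rise lands near the measured ≈ 50 s and motility onset follows
it (≈ 69 s); the study's ≈ 40 s motility onset cannot precede the cAMP
half-rise in a model where motility is downstream of cAMP, so the ordering
constraint wins over the printed 40 s.

Integration is explicit Euler at dt = 5 ms over 180 s, deterministic and
RNG-free; a step-halving convergence check bounds the discretisation error
below 1%. Event timestamps: hyperpolarization onset (V_m 2 mV below
rest), alkalization onset (pH_i 0.01 above rest), cAMP half-rise (midpoint
crossing, only when the trace rises by more than 5%), motility onset. In
the 30-mM K⁺ control no threshold is crossed, so pH_i, cAMP and motility
stay at baseline for any parameter set that leaves external K⁺ unchanged.

Caged-cAMP photorelease uses a declared saturating form
`released = c_max(1 − exp(−αE))` calibrated so the default energy range
spans the reported 5.3–342 nM window (the underlying photochemistry is
abstracted). Latency to motility after instantaneous release integrates
PKA occupancy against the decaying cAMP (τ = 0.35 s) until an accumulated
0.1 s of occupancy-time: saturating release gives ≈ 0.1 s, and latency is
monotone nonincreasing in dose, with non-responders at infinity.

## Motility scoring (`sacph.motility`)

The original analysis software is unpublished; thresholds here are
declared tunables. Frames are binarized with Otsu's threshold computed on
the frame normalized to its maximum (so masks are invariant under global
intensity scaling; constant frames give an empty mask). The global
motility score counts pixels that change between consecutive binarized
frames; the aggregate divides the mean change count by the raw stack's
mean pixel intensity as a sperm-density proxy.

Per-cell analysis detects blobs (connected components with area ≥ 4 px),
links them frame-to-frame by greedy nearest-neighbour within 3 cell
diameters (diameter from the median blob area), and bridges up to 2 missed
frames by linear interpolation so transient blob merges do not sever
tracks. A track is motile when its path diameter within a 1-s sliding
window (largest displacement between any two positions at most a window
apart — robust to direction reversals at the field edge) exceeds 2 cell
diameters, pro-rated for shorter tracks. Percent motile weights tracks by
their length in frames, so a cell whose track fragments contributes the
same as an unbroken one; this removed a ≈ 7-point static bias at the
740-cell density. Response latency after a flash frame is the onset of the
first sustained (two consecutive frames) supra-threshold step, in seconds;
non-responders get infinite latency.

## Synthetic data (`sacph.synth`)

Every generator takes an explicit seed and a named immutable preset, and
emits a machine-readable truth table; identical seed and preset give
bit-identical output. Noise families are fixed: multiplicative lognormal
for plates (parameterised by arithmetic mean and SD), additive Gaussian
for time courses and titrations, Poisson shot noise for movies. The study
reports SDs and ns but not distributions; these choices are the package's.

Preset parameters are the printed study conditions: activation folds (sea
urchin full-length 5.4 Mg²⁺ / 4.3 Mn²⁺; truncated 1.2 / 2.5; salmon 1.4 /
3.0; rat 2.0-fold by bicarbonate with Mg²⁺, 1.6 / 1.3 by pH), turnover
means and SDs (0.035 ± 0.013 at pH 7.2, n = 17; 0.106 ± 0.041 at pH 8.0,
n = 20, MgATP), resting pH_i 6.84 ± 0.02, the cAMP time course (baseline
0.23, plateau 15.1 pmol·(10⁸ cells)⁻¹, half-time 50 s), and the motility
counts (87.5% of 740 cells motile over three movies; 412 of 429 cells
responding within ≈ 100 ms). Turnover means at pH 6.7 and 7.0 are not
printed and are derived from the narrative biphasic shape relative to the
7.2 baseline (0.050 and 0.070, narrative-derived). Sequence presets plant
genotype letters at the K95/R176 positions and apply substitutions
(rate 0.03) and short indels (density 0.005) outside protected windows
around the planted sites and loop motifs, mirroring the biological
conservation of functional sites.

Synthetic movies place Gaussian-blob cells (σ = 1.5 px, amplitude 80, a
near-black background of 0.1 counts as in dark-field imaging) with motile
cells on a persistent random walk (3 px/frame, heading diffusion 0.2 rad)
and static cells jittering at 0.15 px, Poisson-sampled. Movie sizes
(512×512, ~30 frames at 25 or 40 Hz) were chosen so three movies carry the
printed 740 cells at realistic density.

### What the generators do not emulate

Plates have no edge effects, drift or batch structure; traces have white
noise only; titrations are exactly linear in pH; movies contain point-like
cells without flagellar shapes, focus drift, uneven illumination or
photobleaching, and motile cells do not interact. Recovery tests therefore
demonstrate estimator correctness and calibration under the stated noise
models — not robustness to instrument artefacts in real recordings.

## Numerical and degenerate-input conventions

Duplicate pH values in a profile are averaged with a warning; all-tied
rank tests return p = 1 flagged degenerate; readings outside a standard
curve's monotone range return flagged absences; flat traces are flagged
instead of fitted; titrations without a sign change return a
bracket-failure flag; empty panels return empty result tables. Alignment
tie-breaking follows biopython's fixed traceback order, making all calls
deterministic.

## Known limitations

- The cascade is a minimal phenomenological model: no CatSper/Ca²⁺
  dynamics, no channel kinetics beyond the threshold gate, no spatial
  structure along the flagellum.
- Genotype calls inherit alignment uncertainty: at high divergence or
  with indels adjacent to the site windows, a site can map to a gap and
  yield `-` calls; recovery is ≥ 95% at the default indel density by
  construction, not a statement about arbitrary orthologs.
- The motility estimator's accuracy degrades above roughly one cell per
  1,000 px² as blob merges dominate; the synthetic presets sit below that.
- Printed quantities that the study leaves unreconciled (a ~66-fold cAMP
  rise described as "fivefold"; Mn²⁺ turnover ~300× the Mg²⁺ scale) are
  stored as given, per preset, and never forced into consistency.
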