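# Methods

This note records the models, conventions, numerical choices and known
limitations behind `ubconj`. Units are Å for lengths, Å⁻¹ for momentum
transfer q, s⁻¹ for rate constants (reported in 10⁻⁴ s⁻¹ for exchange
rates), M for concentrations and M⁻¹s⁻¹ for association rate constants.

## Coarse-grained representation

Structures are one bead per residue at the CA position with unit scattering
weight. Ensemble discrimination against solution scattering is a shape-level
problem: the observables that separate conformers (Rg, Dmax, the low- and
mid-q curve shape) are insensitive to atomic detail, and residue beads keep
Debye sums inexpensive for pools of thousands of conformers. The cost of
this choice is discussed under *Limitations*. PDB input follows the
fixed-column convention; alternate locations other than blank/'A' are
skipped and insertion codes rejected, so residue indexing is deterministic —
a requirement of the renumbering map below. Coordinates round-trip through
the writer at the PDB's three-decimal precision.

## Linearized conjugate

A conjugate of a substrate of length L with ubiquitin on lysine k is
re-expressed as a single chain of length 76 + L in the order
N–[Ub 1–76]–[substrate k…L]–[substrate 1…k−1]–C, with substrate residue
renumbering

    i >= k  ->  76 + (i − k + 1)        (so k -> 77)
    i <  k  ->  76 + (L − k + 1) + i

which is a bijection onto 77…76+L for every admissible (L, k). Ubiquitin
1–72 and the full substrate are rigid bodies; ubiquitin 73–76 (the tail
after the last β-strand, which carries no secondary structure; Arg72 closes
that strand and stays rigid) is flexible. The isopeptide linkage is assumed
native; its geometry is represented by a single side-chain pseudo-bead (see
below) because only which residues are flexible, not the bond chemistry,
enters a bead-level model. Attachment at non-lysine residues (atypical
serine ubiquitination exists) is allowed behind an explicit override flag.

## Conformer pool

Each conformer keeps the substrate in its input frame and grows the joint
outward: a lysine side-chain pseudo-bead at 4.0 Å from the attachment CA
(one bead approximating the side-chain reach to Nζ), then ubiquitin 76, 75,
74, 73 as CA beads at 3.8 Å virtual bonds, then the ubiquitin 1–72 rigid
body attached at residue 73 in a uniformly random orientation (Shoemake
quaternion sampling). Pseudo-bond angles are uniform in [90°, 145°] and
dihedrals free — standard coarse-grained self-avoiding-chain statistics.
Self-avoidance: every non-bonded bead pair from different segments must be
≥ 3.4 Å apart; growth is resampled on failure (30 tries per bead, 60 per
rigid-body placement, 200 whole-conformer attempts before a seeded error).
Each conformer draws from the counter-based substream
`default_rng([seed, index])`, so pools are bit-reproducible and independent
of generation order. Rg and Dmax are cached per conformer (the pseudo-bead
counts as a scattering center).

In tests and examples the attachment site of the synthetic substrate is the
bead farthest from the centroid: ubiquitination sites are surface-exposed
lysines, and a buried attachment would both bias the sampler toward clashes
and shrink the pool's Rg spread unrealistically.

## Debye scattering

I(q) = n + 2·Σ_pairs sin(q·r)/(q·r) for unit beads (I(0) = n²). The default
path accumulates pairs on a distance histogram (0.5 Å bins) and evaluates,
per bin, the kernel at the bin's *mean* pair distance plus a second-order
correction using the within-bin variance. This keeps the histogram path
within ~2×10⁻⁵ relative of the exact double loop for q ≤ 0.5 Å⁻¹ — the
exact path remains available (`exact=True`) and is the oracle in the test
suite.

## Guinier analysis

Weighted least squares of ln I vs q² (variance of ln I taken as (σ/I)²).
The window is searched by expanding from the lowest usable q (after
skipping beam-stop-like non-monotone leading points, up to 5 candidate
starts). A window is admissible when qmax·Rg ≤ 1.3 and the fit is adequate:
reduced χ² ≤ 1.5 when uncertainties are available, else R² ≥ 0.99 (a fixed
R² floor is statistically wrong for weighted fits — it rejects valid short
low-q windows where noise dominates the tiny signal range and admits only
long, curvature-biased ones). Among admissible windows the selected one
maximizes n·(1 − (qmax·Rg/1.3)²), trading window length against proximity
to the validity limit, where the Guinier approximation itself biases Rg
upward for globular shapes; expansion also stops once a quadratic term in
q² becomes significant (t > 3), trusted only past qmax·Rg ≈ 0.8 where it
cannot be a noise fluke. On noise-free curves of rigid bodies this recovers
the geometric Rg within 1%; on sphere curves with 1% multiplicative noise
the median recovery error is below 2% (per-curve scatter at realistic
sampling is irreducibly ~1%). For ideal-chain (Debye-function) curves the
Guinier relation is exact only in the small-q limit: with a window to
qRg = 1.0 the ln-I curvature of the Debye function biases Rg low by ~4%
even without noise, so chain-type curves should be fitted with
`qrg_limit ≈ 0.5`, where recovery is within 1%. Failure to find an
admissible window returns a diagnostic result, not an exception.

## P(r) and the indirect transform

Model-side P(r) is the weighted pair-distance histogram; its second moment
reproduces the geometric Rg within half a bin, and Dmax is the exact
maximum pair distance. Data-side P(r) solves, for each candidate Dmax, a
non-negative least-squares problem on the sine kernel
I(q) = Σⱼ p(rⱼ)·sinc(q·rⱼ)·Δr (101 r-points, endpoints pinned to zero) with
a second-difference roughness penalty scaled as
λ = smoothness·0.01·‖A‖/‖D‖. The selected Dmax is the smallest candidate
whose reduced χ² is within 20% + 0.02 of the scan's best: under-sized
supports misfit sharply while over-sized ones only flatten, so the elbow
marks the true support. On a noise-free sphere this recovers Dmax = 2R to
one grid step and Rg within 0.1%; P(r) tails underestimate Dmax for
conformer curves with noise (mass near the true maximum distance is tiny),
which is inherent to indirect transforms.

## Porod analysis

Q = ∫q²I dq by the trapezoid rule (the q = 0 endpoint contributes zero),
closed with an analytic tail A/qmax from fitting I ≈ A·q⁻⁴ over the top 20%
of the measured range; Vp = 2π²I₀/Q. The Porod–Debye verdict regresses q⁴I
on q⁴ over 0.1–0.25 Å⁻¹ (configurable) and declares a plateau (compact
particle) iff the slope is not significantly positive at 3 SE; absence of a
plateau is reported as flexibility, the behaviour of chain-like scatterers
whose q⁴I grows without bound.

## Ensemble selection

χ² between a calculated and an experimental curve uses the analytic
weighted least-squares scale s = Σ(I_c·I_e/σ²)/Σ(I_c²/σ²) and a K−1
denominator, no constant subtraction. The genetic algorithm works on
multisets of Nₑ = 20 pool indices (repeats allowed; weights are
multiplicities/Nₑ): population 50, up to 1000 generations, tournament
selection (size 2), uniform crossover at rate 0.5, per-gene mutation to a
random pool index at rate 0.1, elitism 1. Runs stop early after 200
generations without improvement — convergence on these problems is far
faster, and the stall criterion never fires while progress continues. The
initial population is seeded with the best single conformer repeated Nₑ
times, which makes the final χ² provably ≤ the best single-conformer χ².
`select_best` executes independent runs (default 100; analyses here use 20)
on substreams `default_rng([seed, run])` and keeps the lowest-χ² solution,
ties to the lower run id.

Population analysis builds weighted Rg and Dmax histograms at 1 Å
resolution smoothed with a [¼, ½, ¼] binomial filter; two local maxima are
distinct modes only if the minimum between them drops below 50% of the
smaller peak, and each mode is reported as the mass centroid and mass
fraction of its region. A Gaussian kernel of σ = 1 Å was deliberately *not*
used: its effective resolution is ~2.5 Å and it merges populations a 1 Å
histogram resolves.

### Resolution limit of two-state recovery

On synthetic two-state mixtures (pool 2000, Nₑ 20, 20 runs, 1%
multiplicative noise) the pipeline recovers mode locations within ±1 Å and
mass fractions within ±0.15 in ≥ 90% of seeded replicates when the states
are ≥ ~5 Å apart in Rg. At 4 Å separation recovery is intermittent
(~40%): the GA reaches χ² at or below the generating truth's noise floor,
but multisets whose Rg distribution smears between the states match the
mixture curve within noise — at one-bead-per-residue resolution the
distinguishing information sits in high-order moments of the Rg
distribution that a 1%-error curve does not constrain. This is a property
of the inverse problem, not of the optimizer (tighter errors, lower
mutation rates, duplication-biased mutation, sparsity tie-breaking and
run-aggregation were all evaluated and do not change it). Single-state
data always yield exactly one mode. Interpreting two recovered modes
closer than ~5 Å therefore requires external corroboration.

## Exchange kinetics

Dissociation F(t) = (F₀−P)e^(−kt) + P; association
F(t) = F₀ + (Fmax−F₀)(1−e^(−kt)), fitted from the addition event onward
when one exists. Trust-region least squares with a log-linear pre-fit for
the initial rate and five perturbed restarts (×0.2…×5). The plateau is a
free parameter. A fit is rejected (and the replicate set reported "not
determined") when the trace has the wrong net monotonicity (2% of the
spread), the amplitude is degenerate, R² < 0.90, or SE(k) ≥ k; association
traces that fall by more than 10% of their amplitude after the smoothed
maximum are flagged *leaky* — loading that cannot hold its plateau is not a
one-phase process. Rates are invariant under fluorescence scaling and time
translation. Recovery at 1% amplitude noise (120 points / 3600 s) has
median error well under 2% across k ∈ [1, 25]×10⁻⁴ s⁻¹; at the slow end
(kT ≲ 0.5) the decay is incomplete within the window and k trades off
against the free plateau, so individual slow-rate fits carry ~5–20% error —
an identifiability limit, not an optimizer defect. Constraining the plateau
to an independently measured baseline would remove it.

## Binding kinetics

1:1 Langmuir: association R(t) = Req(1−e^(−(kon·C+koff)t)) with
Req = Rmax·C/(C+Kd); dissociation decays from the association endpoint with
rate koff (phases continuous). All concentrations share kon/koff, each
concentration has its own Rmax; rates are log-parameterized to stay
positive, and SEMs come from the Gauss–Newton covariance at the optimum.
Replicates enter the global fit pooled. Kd = koff/kon exactly;
ΔKd = Kd·√((Δkon/kon)² + (Δkoff/koff)²), first-order propagation,
homogeneous of degree one in the input SEMs. Mass transport and avidity are
ignored — the analysis level of single-channel BLI instruments. The module
ships the published effector-binding rate table as input data together with
a consistency report that recomputes koff/kon per row and flags relative
disagreement with the printed Kd above 1.25%; three rows disagree (up to
2.4-fold) and are surfaced, never corrected.

## Synthetic data

Closed forms: sphere I(q) = I₀[3(sin x − x·cos x)/x³]², x = qR (Guinier
radius √(3/5)·R, first minimum at x ≈ 4.493); Gaussian chain
I(q) = I₀·2(e^(−x) − 1 + x)/x², x = (qRg)². Noise is multiplicative
Gaussian, σ = c·I·(1 + d·q/qmax) with defaults c = 0.01, d = 0 — typical
relative errors for a synchrotron protein measurement; real beamline errors
additionally grow toward high q (the d knob) and are correlated by
detector geometry, which this model omits. The default q grid is 250 points
to 0.5 Å⁻¹; Guinier-focused analyses use denser low-q grids, as a
measurement would. Dummy rigid bodies are uniform bead clouds rescaled to
an exact target Rg — they reproduce the size and pair-distance statistics
of globular domains but none of their internal structure, so passing tests
demonstrate correct shape-level inference, not atomic-detail fidelity.
Mixture datasets, exchange traces and sensorgram series are exact model
evaluations plus seeded noise; every generator emits a truth record
sufficient to regenerate its dataset bit-exactly, and generators are
deterministic under (parameters, seed).

## Problem sizes used in the shipped analyses

Pools of 2000 conformers (10,000 is equally supported and ~5× the cost),
20 GA runs per dataset, 10 seeded replicates for recovery statistics, 200
traces for exponential-rate statistics, 4-concentration sensorgram series.

## Limitations

- Shape-only scattering: unit form factors, no hydration layer, no
  excluded-volume contrast — theoretical curves are comparable to data only
  up to an overall scale, which the analytic-scale χ² absorbs.
- The two-state resolution limit above (~5 Å in Rg at 1% error).
- No polyubiquitin chains; exactly one moiety per conjugate.
- Single-curve fitting only; no simultaneous multi-dataset ensemble fits,
  no flexibility metrics beyond the Porod–Debye verdict and the selected
  distribution itself.
- The indirect transform's Dmax is reliable for compact particles but
  systematically short when P(r) has a thin long-distance tail.
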