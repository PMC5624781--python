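# ubconj

Ensemble SAXS modelling and binding/exchange kinetics for site-specifically
monoubiquitinated small GTPases.

## The problem

Attaching a single ubiquitin to a lysine of a GTPase such as Rab5 creates a
branched protein whose ubiquitin moiety is mobile: a single crystal structure
cannot describe it, but solution small-angle X-ray scattering (SAXS) can, if
the measured curve is interpreted as an average over a conformational
ensemble. The same modification also perturbs the protein's working cycle,
which is quantified by nucleotide-exchange fluorescence kinetics and by
effector-binding kinetics. `ubconj` implements that complete analysis as a
reusable, tested Python library for structural biologists working on
ubiquitin conjugates (or any two-rigid-body protein with a short flexible
linker):

1. **Branched → linear representation** — the conjugate is rewritten as one
   chain: ubiquitin 1–76 first, then the substrate from the attachment lysine
   K (renumbered to 77) to its C-terminus, then the N-terminal rest. The
   ubiquitin tail 73–76 plus a lysine side-chain pseudo-bead form the
   flexible joint; everything else is rigid.
2. **Conformer pools** — thousands of self-avoiding random-linker conformers
   (one bead per residue at the CA position).
3. **Debye scattering and curve processing** — theoretical curves
   I(q) = Σᵢⱼ sin(q·rᵢⱼ)/(q·rᵢⱼ) on a pair-distance histogram; Guinier
   analysis (ln I = ln I₀ − q²Rg²/3) with automatic window selection; P(r) by
   regularized indirect transform; Porod invariant Q = ∫q²I dq and volume
   Vp = 2π²I₀/Q; Porod–Debye flexibility verdict (plateau of q⁴I vs q⁴).
4. **Genetic-algorithm ensemble selection** — multisets of Nₑ = 20 pool
   members, fitness = −χ² of the averaged curve after analytic scaling, many
   independent runs with best-of selection; weighted Rg/Dmax population
   analysis with mode detection.
5. **Exchange kinetics** — one-phase exponential fits of MANT-GDP release and
   MANT-GTP loading, replicate mean ± SD in 10⁻⁴ s⁻¹, with principled
   "not determined" flagging of traces the model cannot describe.
6. **Binding kinetics** — global 1:1 Langmuir fits of biolayer-interferometry
   sensorgrams (shared kon/koff, per-concentration Rmax),
   Kd = koff/kon, and ΔKd = Kd·√((Δkon/kon)² + (Δkoff/koff)²).

Every stage has a synthetic-data generator with exact ground truth
(`ubconj.synthetic`), so the full pipeline is testable without any
downloads.

## Worked example

```bash
python examples/04_ensemble_selection.py
```

prints (exact numbers depend only on the fixed seeds in the script):

```
generating pool of 2000 conformers and their Debye curves ...
truth: states at Rg 21.8 and 27.2 A, fractions 0.50/0.50
best of 20 GA runs: chi^2 = 0.75 (about 1 means the fit is at the noise level)
  recovered mode at Rg = 22.1 A with mass fraction 0.52
  recovered mode at Rg = 27.0 A with mass fraction 0.48
```

A synthetic "experimental" curve was built as a 50:50 mixture of compact
(Rg ≈ 21.8 Å) and extended (Rg ≈ 27.2 Å) conformers with 1% noise; the
genetic algorithm, knowing nothing of the truth, selected an ensemble whose
Rg distribution shows both states at the right locations with the right
mass fractions, and whose χ² ≈ 1 means the fit sits at the noise level.
The other scripts in `examples/` demonstrate the linearized representation,
pool statistics, Guinier/P(r)/Porod processing, exchange-rate fitting with
ND flagging, and the 1:1 binding fit with the published-table consistency
report, one capability per file.

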