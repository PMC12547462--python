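# Methods

## Scope and model

`taucleave` analyses time-resolved limited-proteolysis MS experiments: a
protease is incubated with a substrate, samples are taken at fixed time
points in replicate, peptides are identified and quantified by a search
engine, and the analysis asks *where* the substrate is cut and *how
cleavage at each site progresses over time*. The bundled study substrate is
the 441-residue 2N4R isoform of human tau, whose amyloid fibril core
(residues 306–378, repeats R3/R4 plus a short stretch after R4) is shielded
in the fibrillar state while the flanking "fuzzy coat" stays accessible.

All coordinates are 1-based and inclusive. A cleavage site is named by its
P1 residue — the residue N-terminal to the scissile bond — so "V256" is the
bond between residues 256 and 257. Valid sites satisfy 1 ≤ p1 ≤ L−1.

## Peptide mapping and site evidence

Peptides are located on the substrate by exact, gapless substring matching;
the identifications come from sequence-database searches with unspecific
enzyme rules, so fuzzy or semi-specific matching is deliberately absent and
Ile/Leu are kept distinct. Every proteolytic product is the result of two
cuts, so an internal match evidences two sites (P1 = end from its
C-terminus, P1 = start−1 from its N-terminus); a match flush with a
substrate terminus evidences one, and substrate termini never count as
cuts. A `c-only` mode that uses only C-terminal evidence is provided for
sensitivity analysis.

Multi-locus peptides (tau's imperfect repeats can produce them) are
excluded from the statistic by default and surfaced in the QC report
(`unique-only`); a `fractional` policy contributes each locus with weight
1/n instead. The conservative default was chosen because there is no
standard convention, and the difference should be visible, not hidden.

## The relative frequency of cuts

For each accepted peptide (score ≥ 50, uniquely mapped):

1. **Gated averages.** Per time point, replicate intensities are averaged
   only if they pass a significance gate against the substrate-alone
   control samples; otherwise the average is set to zero. The gate is a
   one-sided Welch t-test on log2(intensity + 1), experiment replicates vs
   pooled controls, at α = 0.05. Peptides absent from every control are
   digestion products by construction and are called significant when seen
   in ≥ 2 replicates — this detection shortcut avoids degenerate
   zero-variance tests, which otherwise fall back to a strict mean
   comparison. The +1 offset only affects the test, never the ratios.
2. **Ratios.** Average-intensity ratios are taken with the first positive
   average along the ordered time points as reference (ratio 1 there;
   earlier and later zeros stay 0). All-zero peptides contribute nothing.
3. **Per-site sums.** The relative frequency of cuts of a P1 site at a time
   point is the sum of the ratios of all peptides evidencing that site.

Ratios are computed from replicate-averaged intensities (averaged-first),
not per replicate. No multiple-testing correction is applied by default —
one fixed per-comparison α is the field's standard setting here — but a
Benjamini–Hochberg option (within each time point, across peptides) exists;
since BH-adjusted p-values are never smaller than raw ones, it can only be
stricter.

Useful invariants: frequencies are nonnegative; each peptide's contribution
is invariant to rescaling its raw intensities; adding evidence never
decreases a cell. The implementation is tested cell-for-cell against an
independent straight-line rendering of the procedure on randomized small
instances.

**Site counts** per time point tally sites with positive frequency at that
time point; a cumulative mode counts sites positive at any earlier time
point too. Per-time-point is the default because a site list is most
naturally read per sample.

## Fragments, classes, specificity, comparisons

*Fragments.* Peptides that align without gaps are grouped: intervals that
overlap **or directly abut** merge (adjacency leaves no uncovered residue,
hence no gap). Merging equals connected components of the boolean coverage
mask, is idempotent and order-independent. Each fragment reports its
peptide count and the distinct sites evidenced by those peptides.

*Classes.* Sites are classified by their maximum frequency over time:
class 1 ≥ 20, class 2 in [10, 20), class 3 in (0, 10), class 4 = 0 (no
product detected). Half-open boundaries make non-integer frequencies (sums
of ratios) classify unambiguously.

*Specificity.* The amino-acid distribution covers five residues each side
of the scissile bond (P5…P1, P1′…P5′); positions outside the substrate are
skipped, shrinking that column's sum.

*Comparisons.* Two frequency matrices are compared per site (Δmax and
per-time differences, with A-only/B-only flags). A segment-swapped
construct is compared on the parent's axis through its position map
(`new_index` ↔ `wt_index`), built by `build_swapped_construct`; the default
reporting axis is wild type. The swap is a direct splice — no linker
residues are inserted, since nothing suggests otherwise.

## Synthetic digests

The generator exists so every stage is testable without any deposited
data. Each bond *i* of each molecule is assigned an exponential cut time
with hazard λ_i (s⁻¹), drawn once per molecule, so cut patterns are nested
across sampling times as in a real sampled reaction; a bond is cut by time
*t* with probability 1 − exp(−λ_i t). Products are the maximal uncut runs.
Because cutting is defined on intact coordinates, products are implicitly
re-cut with the same hazards (secondary digestion). Fibrillar shielding is
a static multiplicative protection factor on hazards of bonds lying inside
the core interval; the real mechanism (dissociation before proteolysis) is
not modelled kinetically because no dissociation rate law is available —
only its net effect on cleavage frequency is.

Default study conditions: 441-residue tau substrate; seven time points
(15 s, 1, 3, 10, 30, 60, 120 min); 3 replicates plus 3 substrate-alone
controls; 10⁴ molecules per reaction; detectable product length 7–100
residues (7 is the usual minimum identifiable peptide length; limited
proteolysis routinely identifies very long products, e.g. a 78-residue
core-spanning fragment); lognormal intensity noise with σ = 0.3 (~30% CV,
typical of label-free MS); identification scores uniform in [60, 300] so
planted truth is never score-filtered (a low-score spike-in option
exercises the filter).

The default hazard landscape is tau-like: class-1 sites at the seven most
efficiently cleaved P1 positions (V256, C291, I308, C322, L376, I392,
L408), class-2 at ten more (L266, I277, I278, V287, S289, I328, L344,
V411, L428, V432), 24 class-3 sites scattered deterministically over
small-hydrophobic residues of the C-terminal half, and zero hazard
throughout the protease-resistant N-terminal half (residues 1–225), which
therefore stays class 4. Hazard tiers are separated by one decade
(2×10⁻³ / 2×10⁻⁴ / 2×10⁻⁵ s⁻¹), mirroring the decade-wide frequency bins
that define the classes: class-1 bonds saturate within the time course,
class-2 reach ~76% conversion, class-3 ~13%.

**Detection limit.** Products below 200 molecules (2% of the default
reaction) in a replicate are not observed there. This parameter matters
more than it looks: the frequency statistic normalises each peptide by its
abundance at first detection, so an unrealistically low detection floor
lets every peptide be first seen at the floor and inflates all ratios
toward abundance/floor, washing out the hazard tiers. A 2% floor gives a
~50-fold usable dynamic range and produces class-1 maximum frequencies of
roughly 20–60 — the scale observed in real digests of this kind.

What the generator does **not** emulate: retention-time or ionisation
effects, missed identification of genuinely present products, match
between runs, contaminants (beyond the optional spike-in), modified
peptides, or explicit fibril dissociation kinetics. Passing tests
therefore show that the statistics behave correctly on data with the
assumed structure, not that any laboratory result is reproduced.

### Truth recovery under the defaults

Sensitivity/precision are measured on site detection; rank recovery as
Spearman ρ between planted hazard and recovered max frequency over all
planted sites (undetected → frequency 0; within-tier hazards are tied, so
ρ measures tier separation). Under the defaults, all seven class-1 plants
are recovered in the class-1–2 band, ρ ≈ 0.84, and with protection 0.1 the
unprotected-minus-protected Δmax is positive for ~97% of core sites — the
soluble-vs-fibrillar contrast. These numbers are recomputed by
`scripts/acceptance.py` and the acceptance test suite; nothing is stored.

## Activity assay

Specific activity = ΔA405 · V / (m · ε · t), with V in ml, m in mg protease,
ε the molar extinction coefficient of free pNA (default 8800 M⁻¹cm⁻¹ at
405 nm; path length folded in, 1 cm assumed — both configurable) and t in
min; when ΔA405 is a per-minute slope, t = 1 by convention. The slope is an
ordinary least-squares fit over a configurable initial window, default the
first 20 min of a 2 h trace (whether published values use initial-window or
full-trace slopes is generally unstated; an initial window is the
conservative choice while substrate is unconsumed). Fold activation is the
ratio of specific activities and is invariant to common rescaling.

## Numerical and engineering choices

- Score filtering is inclusive at the threshold (score ≥ 50 passes).
- Ties and degenerate gates: see the detection shortcut above; a time point
  with no replicate samples is treated as undetected.
- Simulation tallies are fully vectorised (per-molecule cut matrices →
  fragment census via run-length bookkeeping) and agree with a
  per-molecule enumeration oracle; per-molecule fragment lengths always
  sum to L.
- All randomness flows from a single `numpy` generator per run; fixed
  seeds make simulated tables byte-identical and the pipeline is
  deterministic end to end.
- Problem sizes in the test suite and acceptance script (20 seeds × two
  scenarios at 10⁴ molecules; 100 randomized oracle instances; 1000
  interval sets) keep a full run in the low minutes while leaving the
  acceptance margins comfortably wide.

## Known limitations

- Exact matching cannot place peptides with residual modification tags the
  stripping rule does not cover.
- The unique-only default discards repeat-region peptides entirely;
  fractional weighting redistributes rather than resolves that ambiguity.
- Frequency magnitudes depend on the detection floor through the
  first-detection reference; comparisons across instruments with very
  different sensitivity should rely on ranks and classes, not raw values.
- The protection model is static; time-dependent shielding (e.g.
  progressive fibril disassembly) would require a hazard that changes over
  the course of the reaction.
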