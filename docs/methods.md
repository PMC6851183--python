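# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical/design decisions that were genuinely open.

## Informational spectrum

A sequence of length *L* is encoded residue-by-residue with the Veljkovic
electron-ion interaction potential (EIIP) scale — 20 dimensionless values
in [0, 0.126], shipped as `data/eiip_veljkovic.tsv` and always passed
explicitly, so alternative scales are pluggable. Non-canonical residues
raise by default; an optional `mean` policy substitutes the scale mean,
because silent substitution would corrupt spectra invisibly.

The spectrum is |DFT| of the mean-centered series zero-padded to
`pad_length` (default **512**, a power of two above receptor-scale
sequences), reported on the grid *k/N* for *k = 1…N/2*, i.e. (0, 0.5]
cycles per residue. Mean-centering is on by default: it removes the DC
component so the *F*→0 end cannot dominate, and makes
constant-composition sequences map to the all-zero spectrum. Frequencies
are displayed rounded to 3 decimals; a query frequency matches a grid bin
when it lies within half a grid step (1/2N), which makes "F(0.216)"-style
labels independent of pad parity. Note 0.216 itself is not a 512-grid
point; the nearest bins label as 0.215/0.217 and all comparisons carry a
±1-bin tolerance.

The consensus spectrum is the raw element-wise product of member
amplitude spectra computed on a common pad. No per-member normalization
is applied: peak *location*, the quantity of interest, is scale-invariant
under positive rescaling of any member. Signal-to-noise at a frequency is
amplitude ÷ mean amplitude over the whole grid, so a flat spectrum has
S/N 1 everywhere and a single-bin spectrum has S/N equal to the bin
count.

## Peptide scanning

Every window of length `min_window…max_window` (default 10–30, bracketing
CDR3-scale peptides) at every start is treated as its own series,
mean-centered per window, and evaluated by the exact discrete-time
Fourier amplitude at the target frequency rather than by re-padding — so
windows of different lengths are compared at exactly the same frequency.

Ranking uses the per-window **signal-to-noise ratio** (amplitude at the
target over the mean amplitude of the window's own spectrum) by default.
The raw amplitude |Σ x(n)e^(−2πiFn)| grows with window length: windows
extending past a compact signal-carrying region pick up zero-mean noise
that increases the modulus about half the time, which systematically
drags the best window beyond the true region (measured: 46/100 runs
recover a planted 17-mer at Jaccard ≥ 0.6 under amplitude ranking versus
100/100 under S/N ranking). Both scores are computed and reported for
every window; `score="amplitude"` restores the alternative. Ties break
by higher S/N, then shorter window, then smaller start — deterministic
and favoring compact regions. Coordinates are 1-based inclusive
throughout (88–104 ⇒ 17 residues).

## Structure metrics

Files are read with gemmi; the first model is kept, altloc duplicates
resolve to the first occurrence, author residue numbering is preserved
with insertion codes appended, and an optional filter drops waters,
common lipids and monoatomic ions. Selectors mirror contact-table
notation (`A:ARG131:NH2`); resolving a selector whose residue name
disagrees with the residue found at that number is an error, which guards
against numbering drift between related structures.

The activation metric is the distance between chosen backbone carbons
(default Cα, configurable to the carbonyl C — "backbone carbon" is
ambiguous and Cα is the conventional helix-displacement proxy) of a TM3
and a TM6 residue; a helper labels the value active-like/inactive-like by
the nearer of the 10.766 Å (inactive) and 18.084 Å (active) crystal
references.

### Contact classifier

The taxonomy and the rule set are explicit because the published contact
tables of this kind come from proprietary viewers with unpublished
thresholds; defaults were chosen to admit every published row while
remaining configurable:

| rule | default |
|---|---|
| attractive charge (N⁺···O⁻) | ≤ 5.6 Å |
| conventional H-bond H···A | ≤ 2.5 Å, X–H···A ≥ 90° |
| conventional H-bond D···A (no H) | ≤ 3.5 Å |
| carbon H-bond H···A | ≤ 3.1 Å (D···A ≤ 3.8 Å without H) |
| alkyl / π-alkyl | ≤ 5.5 Å |
| amide-π centroid | ≤ 5.5 Å, plane angle ≤ 40° |

Typing is **chemistry-first**: the type a pair can take is fixed by atom
roles (charged-group membership, hydrogen parentage by nearest heavy atom
within 1.3 Å, acceptor = oxygen, per-residue alkyl/ring atom sets carried
in the rule object), and cutoffs only gate emission. This makes the
classifier strictly monotone — enlarging a cutoff can only add contacts
of its type. A positive-group hydrogen reaching a negative-group oxygen
types as the combined "Salt Bridge; Attractive Charge"; the corresponding
heavy-atom attractive-charge record for that same oxygen is then
suppressed (matching published table semantics where the N–O row appears
only for oxygens not already salt-bridged). Structures without hydrogens
fall back to heavy-atom donor–acceptor criteria, and salt bridges degrade
to attractive charge. Aromatic centroids are means of complete ring heavy
atoms (Trp contributes both rings); amide groups are backbone C,O of one
residue with N of the next (C–N ≤ 2 Å guards chain breaks); ring/amide
plane normals come from an SVD plane fit and plane angles are folded to
[0°, 90°]. The heavy-atom carbon H-bond fallback accepts any carbon as
donor; in hydrogen-free crystal structures this over-triggers in packed
interfaces and is the documented price of not placing hydrogens
(protonation logic is out of scope). Output ordering is deterministic:
category, then distance.

## Energetics

`plateau_average` is the arithmetic mean and standard error of the mean
of PMF points inside the plateau window (default 20–30 Å, where a pulled
peptide is fully unbound). The binding free energy is
ΔG = −(plateau − bound), with the bound reference defaulting to the
profile's first point (the initial bound conformation; `global_min`
optional). The bound reference is treated as exact, so the reported SE is
the plateau SE. Kd = C₀·exp(ΔG/RT) with C₀ = 1 M and
R = 1.9872036×10⁻³ kcal·mol⁻¹·K⁻¹; the inverse is exact, and the
`BindingEstimate` container enforces the ΔG↔Kd identity at construction.
At 310 K, ΔG = −7.23 kcal/mol gives Kd ≈ 8.0 μM.

## Synthetic data

`plant_periodic_family` writes a cosine of chosen frequency, amplitude
(EIIP units) and per-member random phase into a sub-region by picking, at
each position, the residue whose EIIP value is nearest the target
waveform; outside the region residues are uniform random. Quantizing to
real residues (rather than injecting real-valued signals) exercises the
true sequence→spectrum path, and per-member phases ensure the family
shares only the frequency — exactly what consensus amplitude analysis can
detect. At amplitude ≥ 2× the EIIP-scale SD (≈0.078) the waveform clips
against the scale's range [0, 0.126], yet the planted frequency still
dominates: this is the module's recovery guarantee, verified at 100
seeded runs. The generator does **not** emulate nanobody framework/CDR
grammar, residue-composition bias, or homology between members, so
passing recovery tests demonstrates the spectral machinery, not
performance on real immunoglobulin sequences.

`synthetic_pair_geometry` builds a minimal two-chain model whose single
inter-chain interaction satisfies exactly one requested contact type
under a given rule set, rigidly placed at random;
`random_two_chain_model` scatters charged/polar/alkyl/aromatic residue
templates in a 9 Å box to hit every classifier branch, including
overlapping and boundary cases. `synthetic_pmf` is a smoothstep well
(bound state at energy 0, plateau at the chosen depth over 20–30 Å) with
optional i.i.d. Gaussian noise; with zero noise the extraction recovers
−depth exactly, which anchors the estimator's consistency tests.

## Problem sizes and determinism

Recovery experiments use 3-member families of length 120 (nanobody
scale), 100 seeds; classifier/oracle agreement uses 1,000 random
geometries; PMF replicates use 200-point profiles, 100 seeds. All
generators are pure functions of their arguments including the seed, and
`numpy.random.default_rng` is the only randomness source. The whole suite
and the acceptance script each run in seconds on one CPU.

## Known limitations

* The EIIP scale is a fixed global property scale; context-dependent
  encodings are out of scope.
* The contact classifier is a geometric approximation with explicit
  thresholds; it does not claim equivalence to any proprietary viewer,
  and without hydrogens its carbon H-bond rule is permissive.
* PMF post-processing assumes the plateau window is genuinely unbound and
  flat; no convergence diagnostics beyond the plateau SE are computed.
* Single structures only; no trajectory analysis, docking, simulation, or
  protonation logic.
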