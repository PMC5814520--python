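# Methods

This note documents the models, numerical choices and limitations behind
`xlinkquant`. It states nothing the test suite or `scripts/acceptance.py`
does not itself compute.

## Mass bookkeeping

All arithmetic is monoisotopic; average masses are unsupported because the
workflow targets high-resolution Orbitrap data. Residue masses are fixed in
code at 5-decimal precision so results are bit-stable. Constants: proton
1.007276 Da, water 18.010565 Da, ¹³C–¹²C spacing 1.003355 Da. The BS³
spacer — what remains bridging the two peptides once both NHS esters have
reacted — is C₈H₁₀O₂ = 138.06808 Da. The derived modification set:

| name      | composition            | Δm (Da)    | meaning                          |
|-----------|------------------------|------------|----------------------------------|
| `K_xlink` | spacer − K residue + H₂O | +27.98368 | inserted lysine of a linear form |
| `bs3oh`   | spacer + H₂O           | +156.07864 | hydrolyzed mono-link             |
| `bs3nh2`  | spacer + NH₃           | +155.09463 | aminated mono-link               |
| `bs3loop` | spacer                 | +138.06808 | loop-link                        |

Full precision is carried everywhere; the `.ssl` text renders deltas with 5
decimals. Positions are 1-based within a peptide; 0 denotes the N-terminus.
The isotope envelope is limited to three peaks (M, M+1, M+2), the standard
MS1-filtering choice; the count is configurable.

## Linearization

A cross-link PSM (peptides α, β with link sites) maps to the sequence
`first + "K" + second` with `K_xlink` on the inserted lysine. The bridge
mass lives entirely on that inserted residue; the linked residues
themselves carry nothing extra — this is exactly what closes the mass
identity (inserted K + 27.98368 − water = spacer), and mass equivalence to
the cross-linked species is asserted to < 1e-4 Da on every conversion.

Peptide order in the linear sequence is a free choice (there is no
physically preferred rendering), so a deterministic canonical rule is used:
lexicographically smaller peptide string first, ties broken by smaller link
site. This makes identical cross-links from different runs collapse to one
feature key. An N-terminal modification of the second peptide is re-mapped
onto its first residue, since that terminus no longer exists after
concatenation; a position collision after re-mapping is rejected as
malformed input. Decoy PSMs (reversed-sequence matches) flow through
linearization unchanged and are excluded only at the quantitation gate.

## XIC extraction and peak integration

Per isotope k the trace value at each MS1 spectrum is the sum of centroid
intensities within ±`tolerance` (default 0.055 m/z) of
`mono_mz + k·1.003355/z`. Precursors outside the acquisition range
(m/z 400–1600) are flagged unquantifiable rather than raising. Profile-mode
spectra are rejected; the package quantifies centroided data only.

Peak picking replaces interactive boundary curation with a deterministic
rule: the summed-isotope trace is smoothed with a 5-point moving average;
the apex is the smoothed local maximum nearest the seed RT within ±2 min,
after discarding candidates below 5% of the strongest candidate in the
window (otherwise a noise blip closer to the seed can win over the real
peak); boundaries extend outward while the smoothed trace stays above 1% of
the apex and keeps falling (a valley stops them); the area is the
trapezoidal integral of the *raw* summed trace between the boundaries.
On sampled noiseless Gaussians this recovers the analytic area to well
within 1% (the 1%-of-apex cutoff alone leaves ≈ 0.24% of a Gaussian
outside the boundaries).

A feature counts as *quantified* in a run when its area exceeds a
noise-floor-equivalent area: the median of the bottom decile of the
positive trace intensities times the peak width. Positive values only —
centroided traces are mostly exact zeros, which carry no information about
the noise level.

## Retention-time alignment and match between runs

The run with the most anchor features (features identified in ≥ 2 runs) is
the reference; every other run is mapped onto its RT axis by a Theil–Sen
linear fit of reference vs own anchor apexes (a pure median shift when only
3 anchors are shared or the fit degenerates; identity with a warning below
3). For a run lacking an identification, the seed is the aligned median
apex RT of the runs that have one, mapped back through the inverse of that
run's linear transform. Linear alignment is sufficient for the drifts the
generator emulates; real nonlinear gradient distortions would need a
monotone spline and are a known limitation.

## Statistics and filters

* Feature CV: 100·sd/mean over replicas, sample (n−1) standard deviation —
  the common convention at n = 10.
* Residue-pair CV: median of member-feature CVs (midpoint rule for even
  counts). Means are also emitted.
* "Fully separated in the LC dimension" is operationalized as zero overlap
  of integrated [start, end] peak boundaries in every run: a residue pair
  is dropped when any of its features shares (linear sequence, charge) —
  hence exactly the same m/z — with a feature of a different residue pair
  and their boundaries overlap in any run.
* Complete quantitation: a pair is kept only if every member feature is
  quantified (area above the noise floor) in all replicas.
* Saturation curves average the union size over all C(n, k) subsets
  exhaustively for n ≤ 10 (at most 252 unions); seeded Monte Carlo above.
* Distance filter: pairs at ≥ 30 Å are removed (strict at the boundary);
  pairs with an unresolved residue (no Cα) are retained — they cannot be
  falsified — and logged. A sequence→structure numbering offset is
  configurable (default 0).
* Decoy FDR is reported as 100·decoys/total together with both raw counts,
  so a reader can apply an alternative estimator to the same numbers.
* Percentages are reported to one decimal.

## Synthetic worlds

The generator emulates replicate MS1 acquisitions of a single
BS³-cross-linked tryptic protein:

* Random protein (default 360 aa) assembled from tryptic blocks; in-silico
  digestion uses trypsin KR-not-before-P with up to 4 missed cleavages and
  peptide length bounds 6–60.
* Default world: 55 cross-linked residue pairs (features get the smallest
  charge 3–7 that puts the precursor inside m/z 400–1600; ~30% get a second
  charge state), base areas log-uniform over 10⁵–10⁸, apexes uniform over a
  20-min gradient sampled at a 3 s MS1 cycle, Gaussian elution with
  σ = 0.15 min, a 3-peak isotope envelope with a crude mass-dependent
  abundance heuristic (M+1/M ≈ 0.0005·mass capped at 1.2; deliberately
  non-physical — quantitation sums isotopes, so only the total matters),
  plus a uniform random noise floor. The 20-min gradient is a deliberate
  compaction: it preserves peak shape, sampling density and co-elution
  structure while keeping simulated worlds small.
* Between-replica noise is log-normal multiplicative with σ = √ln(1+CV²),
  so the population CV equals the target: 14% for injection-like replicas
  (repeated injections of one pool; RT jitter sd 0.1 min) and 32% for
  reaction-like replicas (parallel cross-linking reactions; jitter
  0.3 min), plus a per-run constant RT offset up to ±0.4 min to exercise
  alignment. An intensity-dependent mode ties each feature's CV linearly to
  its log area (40% → 5% across the area range) for the CV-vs-intensity
  anticorrelation analysis.
* Planted scenarios: one pair of alternative-linkage features 0.05 min
  apart (same sequence and charge, different residue pair — removable only
  by the co-elution filter), one alternative 3 min apart (must survive),
  one feature absent from one run (caught by the complete-quantitation
  filter), three decoy PSMs from the reversed protein, and a toy Cα-only
  PDB in which a configurable number of pairs is displaced beyond 30 Å.
  Identification schedules are Bernoulli(0.7) per run with at least one
  identified run per feature, exercising match between runs.
* Everything is regenerable bit-identically from (parameters, seed); no
  hidden global randomness.

What passing tests on these worlds do **not** show about real data:
chromatographic tailing and fronting, profile-mode peak shapes, dynamic
exclusion and DDA stochasticity beyond the Bernoulli schedule, co-isolation
of near-isobaric background, nonlinear RT drift, and detector saturation
are all absent from the generator, and the isotope abundances are not
physical. The CV-recovery results therefore validate the bookkeeping and
integration machinery, not instrument behavior.

## mzML support

mzML reading and writing are implemented in-package on lxml: the reader is
namespace-aware, accepts 32-/64-bit float binary arrays with zlib or no
compression, converts scan start times to minutes and consumes MS1 spectra
only; the writer emits minimal MS1-only centroid mzML (64-bit, uncompressed
base64, 1-based scan numbers) used by the generator. Round-trips are
covered by tests.

## Known limitations

Cleavable cross-linkers (MS2-resolved) are out of scope, as are MS2-based
quantitation, intensity normalization between runs (raw-area CVs are
reported), missing-value imputation, statistical testing between
experiments, solvent-accessible-surface distances and mmCIF structures.
The `.ssl` modification-text dialect is self-consistent and round-trips
exactly, but no byte-level compatibility with any other generator's output
is claimed.
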