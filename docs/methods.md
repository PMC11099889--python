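# Methods

## Chemistry

Peptide and cross-link masses are standard monoisotopic arithmetic:
neutral peptide mass = Σ residue masses + H₂O + modification deltas, with
element and residue masses taken from pyteomics' NIST tables, the proton
fixed at 1.00727646 Da and the isotope spacing at 1.0033548 Da (the
averagine ¹³C–¹²C convention; full fine-structure envelopes are out of
scope, so the k-th isotope of a z-charged precursor is
m/z + k·1.0033548/z). Built-in modifications are fixed
carbamidomethyl-Cys (+57.02146 Da) and variable Met oxidation
(+15.99491 Da); others can be supplied per peptide or via the linker/mod
config dictionary.

DSBU is modelled as a `LinkerSpec`: intact mass = mass(Bu) + mass(BuUr)
(conservation enforced to 1e-4 Da), reactive toward K/S/T/Y side chains
and the peptide N-terminus (position 1 with an N-term flag). Fragment
enumeration emits a/b/y ions for ordinals 1..n−1 of both peptides; ions
spanning the link site come in three variants — intact (linker + whole
partner peptide), +Bu, +BuUr — the diagnostic doublet of MS-cleavable
urea linkers. a-ions are generated for search-style use but excluded from
EIC validation (only precursor isotopes are extracted). Dead-end /
zero-mass-shift linker fragments are deliberately not generated: their
ion semantics are not well defined for this linker model.

## Spectrum merging

The paper-facing tolerances are the defaults: 0.75 min RT, 0.015 Th
absolute m/z, 0.025 V·s/cm² 1/K0. The grouping algorithm is greedy seeded
clustering: records sorted by descending precursor intensity (falling back
to total fragment intensity when the precursor intensity is unknown; ties
broken by m/z, RT, scan id), the top unassigned record seeds a cluster and
absorbs all unassigned records within all three tolerances *of the seed*.
Measuring against the seed rather than transitively prevents chains from
drifting beyond the stated tolerances, and the deterministic seeding makes
the partition independent of input order (verified by property test and a
brute-force re-implementation on small instances). Consensus fragment
peaks are formed by gap-based binning of the pooled, m/z-sorted peaks
(default 0.02 Th): intensity-weighted mean m/z, summed intensity, so total
intensity is conserved exactly. The consensus 1/K0 is the
intensity-weighted mean of member precursor mobilities (the ion-mobilogram
center); RT apex is the most intense member's RT, or the median when no
precursor intensities are known. Charge is inferred from adjacent isotope
spacings (best z in 1..8 by least mean absolute deviation, unknown if the
best error exceeds 0.01 Th).

MGF output uses a fixed dialect — `TITLE=compound=<id> run=<run>
1/K0=<4 decimals>`, `PEPMASS`, signed `CHARGE`, `RTINSECONDS` — with
fixed float formats chosen to be round-trip idempotent, so
write→read→write is byte-identical. Reading tolerates unknown headers and
missing mobility (records are flagged mobility-unknown, not rejected).

## FDR

XSM tables from all replicate runs are merged (duplicate (run, scan,
cross-link identity) rows dropped; identity is the unordered pair of
(sequence, link position), charge-agnostic) and scored together: at each
distinct score threshold FDR_est = #decoys ≥ t / #targets ≥ t (1.0 with
no targets), q = running minimum from the most permissive threshold
upward, ties sharing one threshold. The estimator is D/T rather than
D/(T+D), the common convention in XL-MS tools; it is marginally more
conservative and is verified against an O(n²) threshold-scan oracle.
Defaults: q ≤ 0.05 and score ≥ 15. A set without decoys yields q = 0
everywhere with a loud "uncalibrated" warning rather than an error, since
externally pre-filtered target-only tables are a legitimate input.

## Libraries and calibration

The ion-mobility library aggregates filtered target XSMs per (cross-link
identity, charge): arithmetic mean 1/K0, observed (min, max) range, and
an extraction window equal to the range width floored at 0.05 V·s/cm²
total (±0.025 — the merge tolerance) so single-observation precursors get
a usable window. Observations are sorted before averaging, making the
aggregation exactly permutation invariant. The precursor identifier
grammar is `<seqA>@<posA>--<seqB>@<posB>/<z>` with the halves in
lexicographic order (swap-invariant).

iRT calibration is per-run ordinary least squares of reference iRT on
observed RT, requiring positive slope (elution order preserved) and ≥ 2
standards; with ≥ 6 standards the single worst standard is refit away if
its residual exceeds 3× the residual SD — a deliberately minimal stand-in
for vendor calibrators, sufficient for short standard series on a linear
gradient. RT prediction inverts the line and reports a window half-width
max(3·SD/slope, 0.5 min); the floor guards near-perfect fits.

## Validation

For each precursor in the filtered XSM set, the consensus iRT is the
median of its XSM RTs projected through each source run's calibration,
and the q-value is the best among its XSMs. EICs of isotopes k = 0, 1, 2
are extracted per run at the **theoretical** cross-link m/z (computed from
the identified sequences; measured precursor m/z carries the search
engine's mass error and would bias 10 ppm windows), inside the
iRT-projected RT window and the library mobility window. The trace grid
is the set of source scan times in the window (no resampling); traces are
compared on their intersection grid. Peak calling: apex of the summed
trace, boundaries by descent to 5 % of apex or a local minimum, noise =
1.4826·MAD of the off-peak region (unit floor when silent), coelution =
minimum pairwise Pearson correlation of the isotope traces within the
boundaries. Detection requires S/N ≥ 3 and coelution ≥ 0.8 — thresholds
chosen here (configurable); the underlying criteria (peak shape, isotope
coelution, S/N) come from targeted-proteomics practice but no universal
numeric values exist.

Verdict: **validated** ⇔ q ≤ α ∧ detected in *all* sample replicates ∧
not detected in any negative control at the matching iRT/mobility
coordinates. Rejection reasons are reported with fixed precedence
(fdr → control → replicates) for deterministic output; zero detections
anywhere yields `not_detected`. Runs in other replicate groups (e.g.
different collision-energy profiles) are reported but not required.
Match-between-runs classifies each (precursor, replicate) as XSM+peak,
peak-only (transferred identification), or no-peak, and reports the
fraction of precursors with XSMs in every replicate versus those rescued
by peak-only transfer. UpSet tables give exclusive intersection counts
(summing to the union size, checked against a per-element oracle).

## Synthetic benchmark

The generator's defaults define the study: 4 technical replicates of one
collision-energy profile plus 1 cross-linker-free control, 20 true DSBU
cross-links and 20 decoy cross-links (reversed sequences keeping the
C-terminal K/R anchor) from a tryptic digest (cleavage after K/R, no
proline exception, ≤ 3 missed cleavages, lengths 5–50; a linked K is
never C-terminal, since linkage blocks cleavage). The carrier is a
*synthetic*, seeded BSA-like sequence embedding two genuine tryptic BSA
peptides (KQTALVELLK, KFWGK) so the canonical benchmark cross-link exists
in the digest; the real P02769 sequence is not shipped.

Per run: iRT→RT through a per-run affine transform (slope ≈ 2.5 iRT/min,
jittered 1 %; intercept ≈ −20 ± 1); elution peaks are Gaussians
(σ = 0.06 min) on a 0.02 min scan grid shared across the three isotopes
(relative abundances 1 / 0.85 / 0.5); 1/K0 = c₀(z) + 0.4·(m/z)/1000
plus 0.005 V·s/cm² jitter, spanning the plausible TIMS range
(~0.7–1.6); m/z jitter 5 ppm; 300 uniform random matrix peaks per run;
10 iRT standards spanning 0–100. DDA stochasticity is a per-(cross-link,
run) identification probability p_xsm = 0.5; decoy XSM scores are drawn
from Normal(18, 6) and targets from Normal(40, 8) (truncated at 0),
chosen so both the score-15 floor and the 5 % global FDR are exercised —
these score distributions are a simulation device, not measured values.
Two true cross-links are additionally planted in the control
("contaminants") and must be rejected by the negative-control criterion.

What passing tests show — and don't: the generator has clean Gaussian
peaks, independent noise, and no chimeric spectra or intensity-dependent
sampling, so closed-loop recovery demonstrates the pipeline's logic
(windows, calibration, verdicts, accounting), not search-engine-level
performance on real LC-TIMS-MS/MS data.

## Numerical and design notes

- All tolerances are absolute except EIC extraction (ppm); the merge m/z
  tolerance is 0.015 Th absolute by design.
- Clusters, libraries, reports, and generated studies are deterministic
  functions of inputs + seed; study generation is byte-reproducible.
- Degenerate inputs: empty EICs and all-zero traces yield
  `detected=false` without error; missing mobility or library entries are
  skipped with warnings; zero-decoy FDR warns loudly.
- The pipeline runner executes requested stages in fixed dependency order,
  skips stages whose outputs are newer than all inputs, and fails by name
  when a requested stage's dependency outputs are absent.
- Problem sizes in tests and the acceptance script (20 cross-links, 5
  runs, ~60-minute simulated gradients at 0.02 min sampling) keep the full
  closed loop comfortably fast while exercising every stage; they are the
  package's chosen benchmark conditions.

## Known limitations

Linear (not LOWESS) RT alignment; no profile-mode peak picking or mass
recalibration (inputs are assumed centroided and calibrated); no native
Bruker raw-file reading (MGF/mzML/CSV only); cleavable linkers other than
two-fragment NHS esters are expressible via `LinkerSpec` but untested;
the 25 % per-search pre-filter of upstream search engines is treated as
upstream — global FDR is computed on whatever records are supplied.
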