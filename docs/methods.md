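# Methods

## The screening model

The screen compares two groups of LC-MS runs: *sample* (extract
incubated with active α-glucosidase) and *control* (heat-denatured
enzyme), prepared in n = 4 replicate pairs. An enzyme binder survives
the wash steps bound to active enzyme and is therefore more abundant in
the sample eluate; a nonspecifically retained compound appears equally
in both. For each compound the per-pair peak area ratio
PAR_i = A_sample,i / A_control,i is computed (replicate i of the sample
group is paired with replicate i of the control group, matching how the
specimens are prepared), summarized as mean and sample SD (n − 1
denominator), and the compound is selected as a ligand when the mean
PAR exceeds 1 *strictly* and a two-tailed two-sample t-test on the raw
areas gives p < 0.05 *strictly*.

Modeling decisions that the screen's published description leaves open,
resolved here:

- **t-test form.** Student's pooled-variance test on raw (not
  log-transformed) areas is the default; Welch and log-scale variants
  are flags. Degenerate zero-variance input is resolved by convention
  (identical constant groups → p = 1; different constant groups → p = 0
  with a warning).
- **PAR aggregation.** Mean of per-pair ratios by default;
  ratio-of-group-means is available (`use_pairing=False`) for
  sensitivity analysis.
- **Multiple testing.** None by default (the selection rule is applied
  per compound across the whole table); Benjamini–Hochberg is available
  as `correction="BH"`.
- **Missing control areas.** A compound absent from a control run is
  the *strongest* binding signal, not a missing observation; its
  control area is imputed at the detection floor (minimum peak height
  100,000 × the median peak width in seconds) and the result is flagged
  `imputed_control`. A missing sample area drops the pair; fewer than
  two usable pairs excludes the compound with a logged reason.

The enzyme-assay utility `inhibition_percent` implements
(A_a − A_b)/A_a × 100% for the spectrophotometric activity assay.

## Feature extraction

Centroided MS1 scans are linked into mass traces greedily, scan by
scan: a centroid joins the open trace whose intensity-weighted m/z
center is nearest within 5 ppm (one centroid per trace per scan);
traces close after 2 consecutive missing scans and must collect ≥ 3
points. Peaks are local maxima with boundaries at the flanking local
minima (or baseline return / trace ends); areas are trapezoidal with
time in seconds. The noise estimate is the median absolute deviation of
off-peak trace points × 1.4826, floored at 1 count, so S/N is defined
even for noise-free synthetic traces. Detection applies the screen's
thresholds — S/N ≥ 3, apex height ≥ 100,000 counts — after boundary
determination, so relaxing either threshold can only add features
(detection is monotone). The vendor-software "intensity tolerance: 30"
parameter has no public algorithmic definition; it is recorded in the
pipeline configuration for provenance and deliberately unused, and the
MAD-based S/N is likewise a documented substitute whose absolute values
are not comparable to the vendor tool's.

## Alignment and consensus

The run with the most features is the alignment reference. Each other
run receives a single RT offset — the median ΔRT of mutual-nearest
accurate-mass matches against the reference — subtracted before
matching; a 30-min gradient with a 0.1-min grouping tolerance needs
only shift correction at this scale, and a hook is left for piecewise
correction. Features are processed in descending height (ties by
ascending m/z) and greedily joined to a consensus when within 5 ppm and
0.1 min; one feature per run per consensus, each feature joins at most
one consensus, and consensus mass/RT are medians over members.
Isotopologue records (mass = another's + k × 1.00336 Da, k ∈ {1, 2},
same RT window, *smaller* total area) are absorbed into their
monoisotopic compound; their areas are discarded rather than summed,
since the monoisotopic trace already quantifies the compound. A heavier
record with the *larger* area is left alone with a warning — a real A+1
satellite of a CHO compound below ~1 kDa is always smaller.

## Mass arithmetic

Atomic masses are pinned in one place (`chem.py`): C = 12 exactly,
H = 1.00782503207, O = 15.99491461956, proton = 1.007276 (all Da).
Formula enumeration sweeps carbon and oxygen counts and solves the
hydrogen range per (C, O) cell; the element floor is C ≥ 1 (an organic
compound must contain carbon — the weakest reading of a "CHO minimum"
that excludes nonsense, consistent with every reported ligand
containing all three elements), the ceiling is the extraction
constraint C90 H190 O90, and RDBE (C − H/2 + 1) is bounded to [0, 40]
by default — wide, because the screen itself applies no explicit RDBE
filter. Candidates are ordered by |ppm error|, ties by (C, H, O)
lexicographic; the ordering is fixed purely for determinism. The
isotope model treats 13C (1.07%) and 18O (0.205%, at A+2) as
independent binomial substitutions and lumps every nominal-offset-k
isotopologue at +k × 1.00336 Da — accurate to a few percent below
~1 kDa, which is all the simulator needs.

## The synthetic-data generator

`simulate_experiment` emulates the study design: 2 × 4 centroided
positive-mode MS1 runs, 30-min duration, m/z 150–1000. Each compound
contributes a Gaussian elution profile at its [M+H]+ m/z plus
isotopologue satellites; per-scan centroids closer than the instrument
resolution limit merge into one intensity-weighted centroid, since a
60,000-resolution analyzer cannot separate ions ~17 ppm apart at
m/z 580 (default merge limit 10 ppm).

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| n_replicate_pairs | 4 | the study design |
| run_duration | 30 min | the gradient program |
| mz_range | 150–1000 | the full-scan range |
| scan_interval | 0.5 s | ≥ 20 points across a peak |
| peak_sigma | 0.05 min (3 s) | typical UPLC width; resolves the closest reported same-mass isomer pair (0.14 min) |
| rt_jitter_sd | 0.02 min | shared per-run shift, plus half-size per-compound wobble |
| intensity_cv | 0.10 | log-normal multiplicative area noise (mean-one) |
| mz_jitter_ppm | 1.0 | consistent with the ≤ 0.9 ppm deviations of the reference standards |
| noise_peak_rate | 5 /scan | spurious centroids, log-normal intensity far below the detection floor |
| nonspecific_binding | 0 | optional uniform control-area floor; not asserted by default |

The area layer is exposed separately (`draw_areas`) and is the exact
draw the spectra are built on: expected control area = base_area,
expected sample area = base_area × enrichment, each multiplied by
independent mean-one log-normal noise, so the per-pair ratio has
expectation ≈ enrichment (exact in the noise-free limit). Statistical
calibration suites run at this layer; the spectra layer adds only
measurement error, which the feature-extraction tests cover separately.

**The phantom library** (`default_phantom_library`) replants the 84
reported ligands (formula, RT, reported PAR mean ± SD) plus 50 random
inert matrix compounds. The binders' four per-pair ratios are laid out
*deterministically* — a fixed zero-mean unit-SD pattern scaled so the
sample mean and SD reproduce the reported values exactly, with control
areas at base — rather than drawn as fresh noise. Rationale: the
reported mean ± SD of every ligand passes the selection rule by its own
arithmetic (worst case p = 0.047), so with deterministic replanting the
end-to-end recovery rate measures pipeline fidelity (detection,
alignment, quantification, annotation); with stochastic noise at the
reported SDs the weakest ligands re-pass their t-test only ~55–75% of
the time and the recovery rate would mostly re-toss those coin flips.
Matrix compounds stay stochastic at the configured cv.

What the generator does **not** emulate: chromatographic tailing and
fronting, ion suppression and matrix effects, saturation, carry-over
between washes, profile-mode peak shapes, MS/MS spectra, and
inter-batch drift beyond a single per-run RT shift. Passing tests
therefore demonstrate correctness of the *computational* pipeline under
idealized peak shapes, not robustness to every instrumental artifact.

## mzML I/O

The package reads and writes centroid-MS1 mzML 1.1 with its own
compact reader/writer (64-bit little-endian arrays, no compression on
write; none/zlib and 32/64-bit floats on read; scan times in minutes or
seconds). Profile-mode spectra are rejected with an explicit message.
The writer's output was cross-validated against an independent mzML
implementation during development; a write→read→write cycle is
byte-stable.

## Determinism

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` children (area noise, RT jitter, per-run
spectra). Identical seed and configuration give byte-identical mzML,
manifests and report CSVs; the run log records the seed and a
parameter hash.

## Knowledge base

`data/ligand_library.csv` is the 84-ligand table (id, RT, formula,
reported detected MW, PAR mean ± SD, name, source, quality flag);
`data/definite_structures.csv` is the 26-compound definite-structure
subset. Files are checksum-verified at load. Three rows (C36, C42,
C53) carry a `detected_mw_placeholder` flag — their printed MW of
exactly 578.0000 is inconsistent with their formula — and one row
(C69) a `detected_mw_outlier` flag (+8.3 ppm); flagged rows are
excluded from mass-consistency audits. Row C72's PAR is printed as
"135 ± 0.02" in the source table, an evident misprint transcribed as
1.35 and flagged `par_printed_135`. Annotation reuses the 0.1-min
grouping tolerance for "same compound" identity; a mass-only match
gets the "\<name\> isomer" convention, with distinct base names joined
by "/".

## Known limitations

- Co-eluting same-mass neighbors bias each other's areas: peak
  boundaries sit at the shared valley, so a small compound 0.2 min
  from a much larger, differently-enriched one has its measured PAR
  pulled toward the neighbor's (the weakest reported ligand loses its
  significance occasionally for exactly this reason). Fixed-window
  integration across runs would trade this for other biases and is not
  implemented.
- The t-test p-value is compared to a label-permutation oracle only at
  n = 10 per group; at n = 4 the permutation distribution has 70 atoms
  and cannot agree with a continuous p-value.
- Only the [M+H]+ adduct (and its inverse) is supported; adduct
  networks, elements beyond C/H/O and isotope fine structure are out
  of scope.
- Absolute S/N values differ from vendor software by construction.
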