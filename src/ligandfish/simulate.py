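"""Ground-truthed synthetic affinity-ultrafiltration LC-MS experiments.

The generator emulates the screen's experimental design: a *sample*
group incubated with active enzyme and a paired *control* group with
heat-denatured enzyme, n replicate pairs each, analysed as centroided
positive-mode MS1 full scans over a 30-min gradient and m/z 150-1000.
Enzyme binders are planted with a sample/control area enrichment > 1;
matrix compounds carry enrichment 1 and model nonspecific retention.

Two layers are exposed:

* :func:`draw_areas` — the stochastic peak-area layer (log-normal
  multiplicative replicate noise around the expected areas), which is
  what the screening statistics consume;
* :func:`simulate_experiment` — full centroided runs built on the same
  draw: Gaussian elution profiles at the [M+H]+ m/z with isotopologue
  satellites, per-run retention-time shifts, per-centroid ppm mass
  error and spurious noise centroids, plus a truth manifest.

Identical seeds give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import (
    MolecularFormula,
    isotope_pattern,
    monoisotopic_mass,
    mz_from_neutral,
)
from .features import CentroidSpectrum

SAMPLE = "sample"
CONTROL = "control"


@dataclass(frozen=True)
class TrueCompound:
    """A planted compound with its ground-truth screen behaviour.

    ``enrichment`` is the expected sample/control peak-area ratio; a
    binder has enrichment > 1.  ``area_cv`` optionally overrides the
    experiment-wide replicate noise for this compound.  ``par_pattern``
    replants a compound's replicate structure deterministically: when
    set (one factor per replicate pair), sample areas are
    ``base_area x par_pattern[i]`` and control areas exactly
    ``base_area``, so the per-pair area ratios reproduce a prescribed
    mean and SD instead of being drawn at random.
    """

    name: str
    formula: MolecularFormula
    retention_time: float  # min
    base_area: float  # counts * s, expected control-group area
    enrichment: float = 1.0
    area_cv: float | None = None
    par_pattern: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.base_area <= 0:
            raise ValueError(f"{self.name}: base_area must be > 0")
        if self.enrichment <= 0:
            raise ValueError(f"{self.name}: enrichment must be > 0")
        if self.par_pattern is not None and min(self.par_pattern) <= 0:
            raise ValueError(f"{self.name}: par_pattern factors must be > 0")

    @property
    def is_binder(self) -> bool:
        return self.enrichment > 1.0


@dataclass(frozen=True)
class ExperimentConfig:
    """Acquisition and noise parameters of a simulated experiment.

    Defaults mirror the screen's design: 4 replicate pairs, a 30-min
    run, m/z 150-1000, 0.5-s MS1 scans (>= 20 points across a peak),
    0.05-min chromatographic sigma (3-s, typical UPLC — narrow enough
    to resolve the closest reported same-mass isomer pair, 0.14 min
    apart), 0.02-min inter-run RT jitter, 10%
    multiplicative replicate noise on areas and 1-ppm centroid mass
    error.
    """

    n_replicate_pairs: int = 4
    run_duration: float = 30.0  # min
    scan_interval: float = 0.5  # s
    mz_range: tuple[float, float] = (150.0, 1000.0)
    peak_sigma: float = 0.05  # min
    rt_jitter_sd: float = 0.02  # min
    intensity_cv: float = 0.1
    mz_jitter_ppm: float = 1.0
    noise_peak_rate: float = 5.0  # spurious centroids per scan
    nonspecific_binding: float = 0.0  # fractional control-area floor
    n_isotopologues: int = 3
    resolution_limit_ppm: float = 10.0  # co-eluting ions closer than this merge
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicate_pairs < 2:
            raise ValueError("n_replicate_pairs must be >= 2")
        if self.run_duration <= 0 or self.scan_interval <= 0:
            raise ValueError("run_duration and scan_interval must be > 0")
        if self.mz_range[0] >= self.mz_range[1]:
            raise ValueError("mz_range must satisfy low < high")
        for name in ("rt_jitter_sd", "intensity_cv", "mz_jitter_ppm",
                     "noise_peak_rate", "nonspecific_binding"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def run_ids(self) -> list[str]:
        return [f"{g}_{i + 1}" for g in (SAMPLE, CONTROL)
                for i in range(self.n_replicate_pairs)]


@dataclass
class TruthManifest:
    """Per-compound ground truth with realized per-run areas and apex RTs."""

    compounds: list[TrueCompound]
    sample_areas: np.ndarray  # (n_compounds, n_pairs)
    control_areas: np.ndarray
    sample_rts: np.ndarray
    control_rts: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        n = self.sample_areas.shape[1]
        rows = []
        for i, c in enumerate(self.compounds):
            row: dict = {
                "name": c.name,
                "formula": str(c.formula),
                "neutral_mass": monoisotopic_mass(c.formula),
                "retention_time": c.retention_time,
                "base_area": c.base_area,
                "enrichment": c.enrichment,
                "is_binder": c.is_binder,
            }
            for j in range(n):
                row[f"area_sample_{j + 1}"] = self.sample_areas[i, j]
                row[f"area_control_{j + 1}"] = self.control_areas[i, j]
                row[f"rt_sample_{j + 1}"] = self.sample_rts[i, j]
                row[f"rt_control_{j + 1}"] = self.control_rts[i, j]
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6g")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with coefficient of
    variation ``cv`` (exactly 1 when cv == 0)."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def draw_areas(
    compounds: list[TrueCompound],
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Realized (sample_areas, control_areas) matrices, shape
    (n_compounds, n_replicate_pairs).

    Expected control area is ``base_area * (1 + nonspecific_binding)``
    and expected sample area ``base_area * (enrichment +
    nonspecific_binding)``, each multiplied by independent mean-one
    log-normal replicate noise, so the per-pair area ratio has
    expectation ≈ enrichment (exact when cv = 0 or nonspecific = 0 in
    the noise-free limit).
    """
    if not compounds:
        raise ValueError("compound list is empty")
    n = config.n_replicate_pairs
    base = np.array([c.base_area for c in compounds])[:, None]
    enr = np.array([c.enrichment for c in compounds])[:, None]
    nsb = config.nonspecific_binding
    sample = np.empty((len(compounds), n))
    control = np.empty((len(compounds), n))
    pattern_rows = []
    for i, c in enumerate(compounds):
        cv = config.intensity_cv if c.area_cv is None else c.area_cv
        sample[i] = _lognormal_factors(rng, cv, n)
        control[i] = _lognormal_factors(rng, cv, n)
        if c.par_pattern is not None:
            if len(c.par_pattern) != n:
                raise ValueError(
                    f"{c.name}: par_pattern has {len(c.par_pattern)} factors "
                    f"for {n} replicate pairs"
                )
            pattern_rows.append(i)
    sample *= base * (enr + nsb)
    control *= base * (1.0 + nsb)
    for i in pattern_rows:
        c = compounds[i]
        sample[i] = c.base_area * np.asarray(c.par_pattern)
        control[i] = c.base_area
    return sample, control


def _assemble_run(
    compounds: list[TrueCompound],
    areas: np.ndarray,
    apex_rts: np.ndarray,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> list[CentroidSpectrum]:
    """Build one centroided run from realized areas/apexes of one replicate."""
    dt_min = config.scan_interval / 60.0
    n_scans = int(math.floor(config.run_duration / dt_min)) + 1
    scan_rts = np.arange(n_scans) * dt_min
    sigma = config.peak_sigma
    lo, hi = config.mz_range

    idx_parts: list[np.ndarray] = []
    mz_parts: list[np.ndarray] = []
    int_parts: list[np.ndarray] = []

    for i, comp in enumerate(compounds):
        pattern = isotope_pattern(comp.formula, config.n_isotopologues)
        apex = apex_rts[i]
        s0 = max(0, int((apex - 5 * sigma) / dt_min))
        s1 = min(n_scans - 1, int((apex + 5 * sigma) / dt_min) + 1)
        if s1 <= s0:
            continue
        window = np.arange(s0, s1 + 1)
        profile = np.exp(-0.5 * ((scan_rts[window] - apex) / sigma) ** 2)
        height = areas[i] / (sigma * 60.0 * math.sqrt(2.0 * math.pi))
        for mass, rel in pattern:
            mz0 = mz_from_neutral(mass)
            if not (lo <= mz0 <= hi):
                continue
            inten = height * rel * profile
            keep = inten >= 10.0
            if not keep.any():
                continue
            m = int(keep.sum())
            jitter = rng.normal(0.0, config.mz_jitter_ppm * 1e-6, m)
            idx_parts.append(window[keep])
            mz_parts.append(mz0 * (1.0 + jitter))
            int_parts.append(inten[keep])

    if config.noise_peak_rate > 0:
        counts = rng.poisson(config.noise_peak_rate, n_scans)
        total = int(counts.sum())
        idx_parts.append(np.repeat(np.arange(n_scans), counts))
        mz_parts.append(rng.uniform(lo, hi, total))
        int_parts.append(rng.lognormal(math.log(2000.0), 1.0, total))

    if idx_parts:
        idx = np.concatenate(idx_parts)
        mz = np.concatenate(mz_parts)
        inten = np.concatenate(int_parts)
    else:
        idx = np.empty(0, dtype=int)
        mz = inten = np.empty(0)
    order = np.lexsort((mz, idx))
    idx, mz, inten = idx[order], mz[order], inten[order]

    run: list[CentroidSpectrum] = []
    bounds = np.searchsorted(idx, np.arange(n_scans + 1))
    for s in range(n_scans):
        a, b = bounds[s], bounds[s + 1]
        smz, sint = mz[a:b], inten[a:b]
        if smz.size > 1:
            # ions closer than the instrument's resolving power appear as a
            # single centroid: intensity-weighted m/z, summed intensity
            dup = np.diff(smz) <= smz[:-1] * config.resolution_limit_ppm * 1e-6
            if dup.any():
                keep = np.concatenate(([True], ~dup))
                grp = np.cumsum(keep) - 1
                tot = np.bincount(grp, weights=sint)
                smz = np.bincount(grp, weights=sint * smz) / tot
                sint = tot
        run.append(CentroidSpectrum(float(scan_rts[s]), smz, sint))
    return run


def simulate_experiment(
    compounds: list[TrueCompound],
    config: ExperimentConfig,
) -> tuple[dict[str, list[CentroidSpectrum]], TruthManifest]:
    """Simulate a paired sample/control experiment.

    Returns ``(runs, manifest)`` where ``runs`` maps run ids
    (``sample_1`` ... ``control_n``) to time-ordered centroided MS1
    scans, and the manifest records every planted compound with its
    realized per-replicate areas and apexes.
    """
    if not compounds:
        raise ValueError("compound list is empty")
    for c in compounds:
        if not (0.0 <= c.retention_time <= config.run_duration):
            raise ValueError(
                f"compound {c.name!r} has RT {c.retention_time} min outside "
                f"the {config.run_duration}-min run"
            )
    children = np.random.SeedSequence(config.seed).spawn(3)
    area_rng = np.random.default_rng(children[0])
    rt_rng = np.random.default_rng(children[1])
    spec_rngs = [np.random.default_rng(s) for s in children[2].spawn(
        2 * config.n_replicate_pairs)]

    sample_areas, control_areas = draw_areas(compounds, config, area_rng)

    n = config.n_replicate_pairs
    n_comp = len(compounds)
    true_rt = np.array([c.retention_time for c in compounds])
    # one shared chromatographic shift per run plus a smaller independent
    # per-compound wobble; both scale with rt_jitter_sd
    run_shift = rt_rng.normal(0.0, config.rt_jitter_sd, 2 * n)
    wobble = rt_rng.normal(0.0, config.rt_jitter_sd / 2.0, (n_comp, 2 * n))
    apexes = np.clip(
        true_rt[:, None] + run_shift[None, :] + wobble, 0.0, config.run_duration
    )
    sample_rts, control_rts = apexes[:, :n], apexes[:, n:]

    runs: dict[str, list[CentroidSpectrum]] = {}
    for j in range(n):
        runs[f"{SAMPLE}_{j + 1}"] = _assemble_run(
            compounds, sample_areas[:, j], sample_rts[:, j], config, spec_rngs[j]
        )
    for j in range(n):
        runs[f"{CONTROL}_{j + 1}"] = _assemble_run(
            compounds, control_areas[:, j], control_rts[:, j], config,
            spec_rngs[n + j]
        )
    manifest = TruthManifest(
        compounds=list(compounds),
        sample_areas=sample_areas,
        control_areas=control_areas,
        sample_rts=sample_rts,
        control_rts=control_rts,
    )
    return runs, manifest


def default_phantom_library(
    n_matrix: int = 50, seed: int = 20260113
) -> list[TrueCompound]:
    """The packaged screen as a simulation scenario.

    Returns the 84 reported ligands re-planted as binders — formula and
    retention time transcribed from the packaged knowledge base,
    enrichment set to the reported mean peak-area ratio, and the four
    per-pair area ratios laid out deterministically so that their
    sample mean and SD reproduce the reported "mean ± SD" exactly —
    plus ``n_matrix`` non-binding matrix compounds (enrichment 1,
    random CHO formulas and retention times, stochastic replicate
    noise).  Replanting the observed replicate moments rather than
    drawing fresh noise makes recovery of the scenario a property of
    the pipeline, not a re-toss of each compound's borderline t-test.
    """
    from .annotate import load_knowledge_base  # local: avoid import cycle

    rng = np.random.default_rng(seed)
    table = load_knowledge_base()
    # zero-mean pattern with unit sample SD (n-1 denominator), n = 4
    z = np.array([-3.0, -1.0, 1.0, 3.0]) / math.sqrt(20.0 / 3.0)
    compounds: list[TrueCompound] = []
    for row in table.itertuples():
        pattern = tuple(row.par_mean + row.par_sd * z)
        compounds.append(
            TrueCompound(
                name=row.name,
                formula=MolecularFormula.from_string(row.formula),
                retention_time=row.rt,
                base_area=float(rng.lognormal(math.log(2e7), 0.5)),
                enrichment=row.par_mean,
                par_pattern=pattern,
            )
        )
    existing = [(monoisotopic_mass(c.formula), c.retention_time)
                for c in compounds]
    k = 0
    while k < n_matrix:
        c = int(rng.integers(8, 31))
        h = int(rng.integers(max(6, c // 2), 2 * c + 3))
        o = int(rng.integers(1, 15))
        f = MolecularFormula(c, h, o)
        mass = monoisotopic_mass(f)
        rt = float(rng.uniform(1.0, 29.0))
        if not (160.0 <= mass <= 950.0):
            continue
        if any(abs(mass - m) / m < 1e-5 and abs(rt - t) < 0.3
               for m, t in existing):
            continue
        compounds.append(
            TrueCompound(
                name=f"matrix_{k + 1:03d}",
                formula=f,
                retention_time=rt,
                base_area=float(rng.lognormal(math.log(2e7), 0.5)),
                enrichment=1.0,
            )
        )
        existing.append((mass, rt))
        k += 1
    return compounds
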