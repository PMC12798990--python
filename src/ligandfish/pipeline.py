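"""End-to-end screening pipeline and report I/O.

``simulate -> detect -> align -> screen -> annotate -> targets`` glued
into one reproducible run: a :class:`PipelineConfig` collects every
tolerance and threshold, :func:`run_pipeline` executes the stages on a
set of centroided runs and returns a report bundle, and
:func:`write_reports` serialises the bundle as CSV files plus a run log
(resolved parameters, seed, parameter hash, package version).
Identical config + seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    AnnotationMatch,
    InclusionEntry,
    annotate_compounds,
    build_inclusion_list,
    inclusion_table,
    reference_library,
)
from .chem import (
    MAX_ELEMENT_COUNTS,
    MassTolerance,
    MolecularFormula,
    enumerate_formulas,
)
from .consensus import (
    ConsensusCompound,
    align_runs,
    collapse_isotopologues,
    consensus_table,
)
from .features import CentroidSpectrum, Feature, extract_features
from .screening import ScreeningResult, screen_compound, select_ligands
from .simulate import CONTROL, SAMPLE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tolerance and threshold of the screen, in one place.

    ``intensity_tolerance`` is recorded for provenance only: it is a
    vendor-software detection parameter with no public algorithmic
    definition, and the reimplemented detector does not use it.
    """

    ppm: float = 5.0
    rt_tol: float = 0.1  # min
    snr_min: float = 3.0
    min_height: float = 100_000.0
    intensity_tolerance: float = 30.0  # recorded, unused
    max_gap: int = 2
    n_replicate_pairs: int = 4
    par_threshold: float = 1.0
    alpha: float = 0.05
    t_variant: str = "student"
    correction: str = "none"
    use_pairing: bool = True
    min_counts: tuple[int, int, int] = (1, 0, 0)
    max_counts: tuple[int, int, int] = MAX_ELEMENT_COUNTS
    rdbe_bounds: tuple[float, float] = (0.0, 40.0)
    rt_window: float = 0.5  # inclusion-list half-window, min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppm <= 0 or self.rt_tol <= 0:
            raise ValueError("ppm and rt_tol must be > 0")
        if self.alpha < 0 or self.alpha > 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.t_variant not in ("student", "welch"):
            raise ValueError(f"unknown t-test variant {self.t_variant!r}")
        if self.correction not in ("none", "BH"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.n_replicate_pairs < 2:
            raise ValueError("n_replicate_pairs must be >= 2")

    @property
    def tol(self) -> MassTolerance:
        return MassTolerance(self.ppm)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def parameter_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("min_counts", "max_counts", "rdbe_bounds"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class ReportBundle:
    """All pipeline products for one screen."""

    config: PipelineConfig
    feature_tables: dict[str, list[Feature]]
    consensus: list[ConsensusCompound]
    results: list[ScreeningResult]
    selected: list[ScreeningResult]
    annotations: dict[str, AnnotationMatch]
    inclusion: list[InclusionEntry]
    control_floor: float


def _check_groups(run_ids: list[str]) -> int:
    n_s = sum(1 for r in run_ids if r.startswith(f"{SAMPLE}_"))
    n_c = sum(1 for r in run_ids if r.startswith(f"{CONTROL}_"))
    if n_s != n_c:
        raise ValueError(
            f"unequal group sizes: {n_s} sample runs vs {n_c} control runs"
        )
    if n_s < 2:
        raise ValueError("need at least 2 replicate pairs")
    return n_s


def detection_floor_area(
    feature_tables: dict[str, list[Feature]], min_height: float
) -> float:
    """Detection-floor peak area: min_height x median peak width (s).

    Used to impute the control area of compounds absent from the
    control group — the most conservative area a just-detectable peak
    could have had.
    """
    widths = [
        (f.rt_end - f.rt_start) * 60.0
        for feats in feature_tables.values()
        for f in feats
    ]
    if not widths:
        return min_height
    return min_height * float(np.median(widths))


def run_pipeline(
    runs: dict[str, list[CentroidSpectrum]],
    config: PipelineConfig = PipelineConfig(),
) -> ReportBundle:
    """Execute detect -> align -> screen -> annotate -> targets."""
    _check_groups(list(runs))

    feature_tables = {
        run_id: extract_features(
            run,
            tol=config.tol,
            snr_min=config.snr_min,
            min_height=config.min_height,
            max_gap=config.max_gap,
            run_id=run_id,
        )
        for run_id, run in runs.items()
    }

    consensus = collapse_isotopologues(
        align_runs(feature_tables, tol=config.tol, rt_tol=config.rt_tol),
        tol=config.tol,
        rt_tol=config.rt_tol,
    )

    floor = detection_floor_area(feature_tables, config.min_height)
    results: list[ScreeningResult] = []
    for c in consensus:
        r = screen_compound(
            c.compound_id,
            c.sample_areas,
            c.control_areas,
            control_floor=floor,
            variant=config.t_variant,
            use_pairing=config.use_pairing,
        )
        if r is None:
            continue
        r.neutral_mass = c.neutral_mass
        r.rt = c.rt
        results.append(r)

    selected = (
        select_ligands(
            results,
            par_threshold=config.par_threshold,
            alpha=config.alpha,
            correction=config.correction,
        )
        if results
        else []
    )

    by_id = {c.compound_id: c for c in consensus}
    library = reference_library()
    sel_compounds = [by_id[r.compound_id] for r in selected]
    matches = annotate_compounds(
        sel_compounds, library, tol=config.tol, rt_tol=config.rt_tol
    )
    annotations = {}
    for r, m in zip(selected, matches):
        r.annotation = m.annotation
        annotations[r.compound_id] = m

    inclusion = build_inclusion_list(sel_compounds, rt_window=config.rt_window)

    return ReportBundle(
        config=config,
        feature_tables=feature_tables,
        consensus=consensus,
        results=results,
        selected=selected,
        annotations=annotations,
        inclusion=inclusion,
        control_floor=floor,
    )


# ---------------------------------------------------------------------------
# report serialisation

FLOAT_FMT = "%.6g"


def features_table(feature_tables: dict[str, list[Feature]]) -> pd.DataFrame:
    rows = [
        {
            "run_id": run_id,
            "mz": f.mz,
            "neutral_mass": f.neutral_mass,
            "rt_apex": f.rt_apex,
            "rt_start": f.rt_start,
            "rt_end": f.rt_end,
            "height": f.height,
            "area": f.area,
            "snr": f.snr,
        }
        for run_id, feats in feature_tables.items()
        for f in feats
    ]
    return pd.DataFrame(
        rows,
        columns=["run_id", "mz", "neutral_mass", "rt_apex", "rt_start",
                 "rt_end", "height", "area", "snr"],
    )


def screening_table(results: list[ScreeningResult], n_pairs: int) -> pd.DataFrame:
    rows = []
    for r in results:
        row: dict = {
            "compound_id": r.compound_id,
            "neutral_mass": r.neutral_mass,
            "rt": r.rt,
        }
        for j in range(n_pairs):
            row[f"par_{j + 1}"] = (
                r.par_values[j] if j < r.par_values.size else np.nan
            )
        row.update(
            par_mean=r.par_mean,
            par_sd=r.par_sd,
            p_value=r.p_value,
            selected=r.selected,
            imputed_control=r.imputed_control,
            annotation=r.annotation,
        )
        rows.append(row)
    cols = ["compound_id", "neutral_mass", "rt"]
    cols += [f"par_{j + 1}" for j in range(n_pairs)]
    cols += ["par_mean", "par_sd", "p_value", "selected", "imputed_control",
             "annotation"]
    return pd.DataFrame(rows, columns=cols)


def annotation_report(bundle: ReportBundle) -> pd.DataFrame:
    """Selected compounds with best CHO formula candidate and annotation."""
    cfg = bundle.config
    rows = []
    for r in bundle.selected:
        cands = enumerate_formulas(
            r.neutral_mass,
            tol=cfg.tol,
            min_counts=MolecularFormula(*cfg.min_counts),
            max_counts=MolecularFormula(*cfg.max_counts),
            rdbe_bounds=cfg.rdbe_bounds,
        )
        best = cands[0] if cands else None
        rows.append(
            {
                "compound_id": r.compound_id,
                "neutral_mass": r.neutral_mass,
                "rt": r.rt,
                "formula": str(best.formula) if best else "",
                "formula_ppm_error": best.ppm_error if best else np.nan,
                "rdbe": best.rdbe if best else np.nan,
                "n_candidates": len(cands),
                "annotation": r.annotation,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["compound_id", "neutral_mass", "rt", "formula",
                 "formula_ppm_error", "rdbe", "n_candidates", "annotation"],
    )


def write_reports(bundle: ReportBundle, directory: str | Path) -> dict[str, Path]:
    """Write the five report CSVs, the resolved config and a run log."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = bundle.config.n_replicate_pairs
    out = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        p = directory / name
        df.to_csv(p, index=False, float_format=FLOAT_FMT)
        out[name] = p

    _write("features.csv", features_table(bundle.feature_tables))
    _write("consensus.csv", consensus_table(bundle.consensus))
    _write("screening.csv", screening_table(bundle.results, n))
    _write("annotations.csv", annotation_report(bundle))
    _write("inclusion_list.csv", inclusion_table(bundle.inclusion))

    bundle.config.to_yaml(directory / "config.yaml")
    out["config.yaml"] = directory / "config.yaml"
    log = {
        "ligandfish_version": __version__,
        "seed": bundle.config.seed,
        "parameter_hash": bundle.config.parameter_hash(),
        "n_runs": len(bundle.feature_tables),
        "n_features": sum(len(v) for v in bundle.feature_tables.values()),
        "n_consensus": len(bundle.consensus),
        "n_screened": len(bundle.results),
        "n_selected": len(bundle.selected),
        "control_floor_area": float(bundle.control_floor),
    }
    with open(directory / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    out["run_log.yaml"] = directory / "run_log.yaml"
    return out


def read_feature_tables(path: str | Path) -> dict[str, list[Feature]]:
    """Inverse of the features.csv layout."""
    df = pd.read_csv(path)
    tables: dict[str, list[Feature]] = {}
    for row in df.itertuples(index=False):
        tables.setdefault(row.run_id, []).append(
            Feature(
                mz=row.mz,
                neutral_mass=row.neutral_mass,
                rt_apex=row.rt_apex,
                rt_start=row.rt_start,
                rt_end=row.rt_end,
                height=row.height,
                area=row.area,
                snr=row.snr,
                run_id=row.run_id,
            )
        )
    return tables


def read_consensus_table(path: str | Path) -> list[ConsensusCompound]:
    """Inverse of the consensus.csv layout."""
    df = pd.read_csv(path)
    n = sum(1 for c in df.columns if c.startswith("area_sample_"))
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ConsensusCompound(
                compound_id=row.compound_id,
                neutral_mass=row.neutral_mass,
                rt=row.rt,
                sample_areas=np.array(
                    [getattr(row, f"area_sample_{j + 1}") for j in range(n)]
                ),
                control_areas=np.array(
                    [getattr(row, f"area_control_{j + 1}") for j in range(n)]
                ),
            )
        )
    return out
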