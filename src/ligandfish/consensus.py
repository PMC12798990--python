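"""Cross-run feature alignment and isotopologue collapse.

Features from the 2 x n replicate runs are matched into consensus
compounds by accurate mass (5 ppm) and retention time (0.1 min) after a
single per-run RT-offset correction, then A+1/A+2 isotopologue records
are merged into their monoisotopic compound.  Each consensus carries a
sample x replicate / control x replicate peak-area matrix (NaN =
missing) — the input of the screening statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import A1_MASS_OFFSET, MassTolerance
from .features import Feature
from .simulate import CONTROL, SAMPLE

logger = logging.getLogger(__name__)

DEFAULT_RT_TOL = 0.1  # min


@dataclass
class ConsensusCompound:
    """One compound aligned across runs.

    ``neutral_mass`` and ``rt`` are medians over member features; the
    area matrices have one entry per replicate (NaN where the compound
    was not found in that run).
    """

    compound_id: str
    neutral_mass: float
    rt: float
    sample_areas: np.ndarray
    control_areas: np.ndarray
    member_features: list[tuple[str, Feature]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return self.sample_areas.size

    def total_area(self) -> float:
        return float(np.nansum(self.sample_areas) + np.nansum(self.control_areas))


def _parse_run_id(run_id: str) -> tuple[str, int]:
    group, _, idx = run_id.rpartition("_")
    if group not in (SAMPLE, CONTROL):
        raise ValueError(f"run id {run_id!r} must look like 'sample_1'/'control_1'")
    return group, int(idx) - 1


def estimate_rt_offset(
    features: list[Feature],
    reference: list[Feature],
    tol: MassTolerance,
    coarse_rt: float = 0.5,
) -> float:
    """Median RT offset of mutual-nearest accurate-mass matches between a
    run and the reference run (to be subtracted from the run's RTs)."""
    if not features or not reference:
        return 0.0
    ref_mass = np.array([f.neutral_mass for f in reference])
    ref_rt = np.array([f.rt_apex for f in reference])
    order = np.argsort(ref_mass)
    ref_mass, ref_rt = ref_mass[order], ref_rt[order]

    def nearest_ref(f: Feature) -> int | None:
        half = tol.window(f.neutral_mass)
        j0 = np.searchsorted(ref_mass, f.neutral_mass - half)
        j1 = np.searchsorted(ref_mass, f.neutral_mass + half)
        best, best_d = None, coarse_rt
        for j in range(j0, j1):
            d = abs(ref_rt[j] - f.rt_apex)
            if d <= best_d:
                best, best_d = j, d
        return best

    deltas = []
    claimed: dict[int, tuple[float, float]] = {}
    for f in features:
        j = nearest_ref(f)
        if j is None:
            continue
        d = abs(ref_rt[j] - f.rt_apex)
        prev = claimed.get(j)
        if prev is None or d < prev[0]:
            claimed[j] = (d, f.rt_apex - ref_rt[j])
    deltas = [v[1] for v in claimed.values()]
    return float(np.median(deltas)) if deltas else 0.0


def align_runs(
    feature_tables: dict[str, list[Feature]],
    tol: MassTolerance = MassTolerance(5.0),
    rt_tol: float = DEFAULT_RT_TOL,
) -> list[ConsensusCompound]:
    """Match features across runs into consensus compounds.

    The run with the most features is the alignment reference; every
    other run gets a single median RT offset subtracted before
    matching.  Features are processed in descending height (ties by
    ascending m/z) and greedily joined to the consensus they match in
    mass and corrected RT — at most one feature per run per consensus,
    and each feature joins at most one consensus.
    """
    if len(feature_tables) < 2:
        raise ValueError("alignment needs at least 2 runs")
    n_pairs = 0
    for run_id in feature_tables:
        _, idx = _parse_run_id(run_id)
        n_pairs = max(n_pairs, idx + 1)

    ref_id = max(feature_tables, key=lambda r: len(feature_tables[r]))
    offsets = {
        run_id: (
            0.0
            if run_id == ref_id
            else estimate_rt_offset(feats, feature_tables[ref_id], tol)
        )
        for run_id, feats in feature_tables.items()
    }

    pool: list[tuple[str, float, Feature]] = []  # (run_id, corrected_rt, feature)
    for run_id, feats in feature_tables.items():
        off = offsets[run_id]
        for f in feats:
            pool.append((run_id, f.rt_apex - off, f))
    pool.sort(key=lambda t: (-t[2].height, t[2].mz))

    # consensus accumulators
    masses: list[float] = []
    rts: list[float] = []
    members: list[list[tuple[str, float, Feature]]] = []

    for run_id, crt, f in pool:
        best, best_ppm = None, tol.ppm
        for k in range(len(masses)):
            dppm = abs(f.neutral_mass - masses[k]) / masses[k] * 1e6
            if dppm <= best_ppm and abs(crt - rts[k]) <= rt_tol:
                if any(r == run_id for r, _, _ in members[k]):
                    continue  # one feature per run per consensus
                best, best_ppm = k, dppm
        if best is None:
            masses.append(f.neutral_mass)
            rts.append(crt)
            members.append([(run_id, crt, f)])
        else:
            members[best].append((run_id, crt, f))
            masses[best] = float(np.median([m.neutral_mass for _, _, m in members[best]]))
            rts[best] = float(np.median([r for _, r, _ in members[best]]))

    out: list[ConsensusCompound] = []
    for k in range(len(masses)):
        sample = np.full(n_pairs, np.nan)
        control = np.full(n_pairs, np.nan)
        for run_id, _, f in members[k]:
            group, idx = _parse_run_id(run_id)
            (sample if group == SAMPLE else control)[idx] = f.area
        out.append(
            ConsensusCompound(
                compound_id="",
                neutral_mass=masses[k],
                rt=rts[k],
                sample_areas=sample,
                control_areas=control,
                member_features=[(r, f) for r, _, f in members[k]],
            )
        )
    out.sort(key=lambda c: (c.rt, c.neutral_mass))
    for i, c in enumerate(out):
        c.compound_id = f"P{i + 1:04d}"
    return out


def collapse_isotopologues(
    consensus: list[ConsensusCompound],
    tol: MassTolerance = MassTolerance(5.0),
    rt_tol: float = DEFAULT_RT_TOL,
) -> list[ConsensusCompound]:
    """Merge A+1/A+2 isotopologue consensus records into their
    monoisotopic compound.

    A record is a satellite of another if its mass equals the other's
    + k x 1.00336 Da (k = 1 or 2, within tolerance), the RT difference
    is within ``rt_tol`` and its total area is smaller.  Satellite
    areas are discarded (the monoisotopic areas already quantify the
    compound); a heavier-but-larger record is left alone with a
    warning, since a real A+1 is always smaller for CHO compounds.
    """
    order = sorted(range(len(consensus)), key=lambda i: consensus[i].neutral_mass)
    absorbed = [False] * len(consensus)
    masses = [consensus[i].neutral_mass for i in order]
    for pos, i in enumerate(order):
        if absorbed[i]:
            continue
        ci = consensus[i]
        for k in (1, 2):
            target = ci.neutral_mass + k * A1_MASS_OFFSET
            half = tol.window(target)
            j0 = np.searchsorted(masses, target - half)
            j1 = np.searchsorted(masses, target + half)
            for jpos in range(j0, j1):
                j = order[jpos]
                if absorbed[j] or j == i:
                    continue
                cj = consensus[j]
                if abs(cj.rt - ci.rt) > rt_tol:
                    continue
                if cj.total_area() < ci.total_area():
                    absorbed[j] = True
                    ci.member_features.extend(cj.member_features)
                else:
                    logger.warning(
                        "heavier record %s (mass %.4f) has larger area than "
                        "%s; not merged",
                        cj.compound_id, cj.neutral_mass, ci.compound_id,
                    )
    return [c for i, c in enumerate(consensus) if not absorbed[i]]


def consensus_table(consensus: list[ConsensusCompound]) -> pd.DataFrame:
    """Flat table: compound_id, neutral_mass, rt, area_sample_i, area_control_i."""
    rows = []
    for c in consensus:
        row: dict = {
            "compound_id": c.compound_id,
            "neutral_mass": c.neutral_mass,
            "rt": c.rt,
        }
        for j in range(c.n_pairs):
            row[f"area_sample_{j + 1}"] = c.sample_areas[j]
            row[f"area_control_{j + 1}"] = c.control_areas[j]
        rows.append(row)
    return pd.DataFrame(rows)
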