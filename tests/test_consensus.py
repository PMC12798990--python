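"""Cross-run alignment and isotopologue collapse."""

import logging

import numpy as np
import pytest

import ligandfish as lf
from ligandfish.chem import A1_MASS_OFFSET, MassTolerance
from ligandfish.consensus import (
    ConsensusCompound,
    align_runs,
    collapse_isotopologues,
)
from ligandfish.features import Feature


def feat(mass, rt, area=1e6, height=1e6, run_id="sample_1"):
    return Feature(
        mz=mass + 1.007276,
        neutral_mass=mass,
        rt_apex=rt,
        rt_start=rt - 0.1,
        rt_end=rt + 0.1,
        height=height,
        area=area,
        snr=50.0,
        run_id=run_id,
    )


def paired_tables(masses_rts, n=4, shift=0.0):
    """The same features replicated across 2 x n runs, optionally with a
    uniform RT shift applied to the last run."""
    tables = {}
    run_ids = [f"sample_{i+1}" for i in range(n)] + [f"control_{i+1}" for i in range(n)]
    for k, rid in enumerate(run_ids):
        off = shift if k == len(run_ids) - 1 else 0.0
        tables[rid] = [feat(m, rt + off, run_id=rid) for m, rt in masses_rts]
    return tables


class TestAlignment:
    def test_uniform_shift_corrected(self):
        planted = [(300.0, 5.0), (400.0, 10.0), (500.0, 15.0)]
        tables = paired_tables(planted, shift=0.05)
        consensus = align_runs(tables)
        assert len(consensus) == len(planted)
        for c in consensus:
            assert not np.isnan(c.sample_areas).any()
            assert not np.isnan(c.control_areas).any()

    def test_rt_tolerance_splits_close_compounds(self):
        tables = paired_tables([(300.0, 5.0)])
        for rid in tables:
            tables[rid].append(feat(300.0, 5.2, run_id=rid))
        consensus = align_runs(tables, rt_tol=0.1)
        assert len(consensus) == 2

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            align_runs({"sample_1": [feat(300.0, 5.0)]})

    def test_no_feature_duplicated_across_consensus(self):
        planted = [(300.0, 5.0), (300.001, 5.05), (500.0, 15.0)]
        tables = paired_tables(planted)
        consensus = align_runs(tables)
        seen = set()
        for c in consensus:
            for rid, f in c.member_features:
                key = (rid, id(f))
                assert key not in seen
                seen.add(key)
        n_in = sum(len(v) for v in tables.values())
        assert len(seen) <= n_in

    def test_realignment_is_fixed_point(self):
        planted = [(300.0, 5.0), (400.0, 10.0)]
        tables = paired_tables(planted, shift=0.04)
        first = align_runs(tables)
        # rebuild per-run tables from consensus members (already corrected)
        again = {rid: [] for rid in tables}
        for c in first:
            for rid, f in c.member_features:
                again[rid].append(f)
        second = align_runs(again)
        assert len(second) == len(first)
        for a, b in zip(
            sorted(first, key=lambda c: c.neutral_mass),
            sorted(second, key=lambda c: c.neutral_mass),
        ):
            assert a.neutral_mass == pytest.approx(b.neutral_mass, abs=1e-9)


def cc(cid, mass, rt, areas):
    return ConsensusCompound(
        compound_id=cid,
        neutral_mass=mass,
        rt=rt,
        sample_areas=np.array(areas, dtype=float),
        control_areas=np.array(areas, dtype=float),
    )


class TestIsotopologueCollapse:
    def test_satellite_merged_into_monoisotopic(self):
        mono = cc("a", 358.1052, 10.0, [1e7] * 4)
        a1 = cc("b", 358.1052 + A1_MASS_OFFSET, 10.0, [2e6] * 4)
        out = collapse_isotopologues([mono, a1])
        assert [c.compound_id for c in out] == ["a"]
        # monoisotopic areas kept, not summed
        assert out[0].sample_areas[0] == 1e7

    def test_rt_guard_prevents_merge(self):
        mono = cc("a", 358.1052, 10.0, [1e7] * 4)
        other = cc("b", 358.1052 + A1_MASS_OFFSET, 10.5, [2e6] * 4)
        assert len(collapse_isotopologues([mono, other])) == 2

    def test_larger_satellite_not_merged(self, caplog):
        mono = cc("a", 358.1052, 10.0, [1e6] * 4)
        heavy = cc("b", 358.1052 + A1_MASS_OFFSET, 10.0, [1e7] * 4)
        with caplog.at_level(logging.WARNING):
            out = collapse_isotopologues([mono, heavy])
        assert len(out) == 2
        assert any("not merged" in r.message for r in caplog.records)

    def test_collapse_is_idempotent(self):
        records = [
            cc("a", 358.1052, 10.0, [1e7] * 4),
            cc("b", 358.1052 + A1_MASS_OFFSET, 10.0, [2e6] * 4),
            cc("c", 500.0, 12.0, [5e6] * 4),
        ]
        once = collapse_isotopologues(records)
        twice = collapse_isotopologues(once)
        assert [c.compound_id for c in twice] == [c.compound_id for c in once]


class TestRecovery:
    def test_default_noise_recovers_full_area_matrices(self):
        """At default noise (10% cv, 0.02-min RT jitter), nearly every
        planted compound yields exactly one consensus with a complete
        2 x 4 area matrix."""
        rng = np.random.default_rng(99)
        compounds = []
        for i in range(20):
            c = int(rng.integers(10, 30))
            h = int(rng.integers(c, 2 * c))
            o = int(rng.integers(2, 12))
            f = lf.MolecularFormula(c, h, o)
            from ligandfish.chem import monoisotopic_mass

            if not 150 < monoisotopic_mass(f) < 900:
                continue
            compounds.append(
                lf.TrueCompound(f"c{i}", f, float(rng.uniform(1, 9)), 3e7, 1.5)
            )
        config = lf.ExperimentConfig(seed=17, run_duration=10.0)
        runs, _ = lf.simulate_experiment(compounds, config)
        tables = {
            rid: lf.extract_features(run, run_id=rid) for rid, run in runs.items()
        }
        consensus = collapse_isotopologues(align_runs(tables))
        from ligandfish.chem import monoisotopic_mass

        full = 0
        for c in compounds:
            m = monoisotopic_mass(c.formula)
            hits = [
                x
                for x in consensus
                if abs(x.neutral_mass - m) / m * 1e6 <= 5
                and abs(x.rt - c.retention_time) <= 0.1
            ]
            if (
                len(hits) == 1
                and not np.isnan(hits[0].sample_areas).any()
                and not np.isnan(hits[0].control_areas).any()
            ):
                full += 1
        assert full >= 0.95 * len(compounds)
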