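"""Compound annotation and targeted-MS/MS inclusion lists.

Selected consensus compounds are matched against a packaged knowledge
base of citrus-peel flavonoid ligands (name, formula, retention time).
A compound matching a library entry in both accurate mass and RT takes
its name; matching in mass only takes the "<name> isomer" convention
(several same-formula base names are joined with "/").  Selected
compounds are finally emitted as a precursor-ion inclusion list for
targeted MS/MS acquisition.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .chem import MassTolerance, MolecularFormula, monoisotopic_mass, mz_from_neutral
from .consensus import ConsensusCompound

logger = logging.getLogger(__name__)

SCAN_RANGE = (150.0, 1000.0)  # instrument full-scan m/z range
DEFAULT_COLLISION_ENERGIES = (30.0, 45.0, 60.0)  # normalized CE (%)
DEFAULT_RT_WINDOW = 0.5  # +/- min around the consensus RT


class KnowledgeBaseError(RuntimeError):
    """Packaged knowledge-base file missing or corrupted."""


def _read_packaged_csv(name: str) -> pd.DataFrame:
    data_dir = resources.files("ligandfish") / "data"
    raw = (data_dir / name).read_bytes()
    checksums = json.loads((data_dir / "checksums.json").read_text())
    digest = hashlib.sha256(raw).hexdigest()
    if digest != checksums[name]:
        raise KnowledgeBaseError(
            f"checksum mismatch for packaged file {name}: "
            f"{digest} != {checksums[name]}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), keep_default_na=False)


def load_knowledge_base() -> pd.DataFrame:
    """The 84-ligand knowledge base.

    Columns: id, rt (min), formula, detected_mw (Da, as reported),
    par_mean, par_sd, name, source (reference_standard | literature)
    and quality_flag (`detected_mw_placeholder` for the three 578.0000
    rows, `detected_mw_outlier` for a reported MW deviating > 5 ppm
    from its formula, `par_printed_135` for one PAR misprint corrected
    to 1.35).
    """
    return _read_packaged_csv("ligand_library.csv")


def load_definite_structures() -> pd.DataFrame:
    """The 26 ligands with definite (fully elucidated) structures."""
    return _read_packaged_csv("definite_structures.csv")


@dataclass(frozen=True)
class ReferenceCompound:
    """A knowledge-base entry used for annotation."""

    name: str
    formula: MolecularFormula
    rt: float | None = None
    source: str = "literature"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("reference compound needs a non-empty name")

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)


def reference_library() -> list[ReferenceCompound]:
    """Knowledge base as :class:`ReferenceCompound` records."""
    table = load_knowledge_base()
    return [
        ReferenceCompound(
            name=row.name,
            formula=MolecularFormula.from_string(row.formula),
            rt=row.rt,
            source=row.source,
        )
        for row in table.itertuples(index=False)
    ]


def _base_name(name: str) -> str:
    return name.removesuffix(" isomer")


@dataclass
class AnnotationMatch:
    """Annotation outcome for one compound."""

    annotation: str
    matched: list[ReferenceCompound] = field(default_factory=list)
    rt_matched: bool = False


def annotate(
    neutral_mass: float,
    rt: float,
    library: list[ReferenceCompound],
    tol: MassTolerance = MassTolerance(5.0),
    rt_tol: float = 0.1,
) -> AnnotationMatch:
    """Annotate one (mass, RT) observation against the library.

    Mass + RT match -> the entry's name (nearest |ppm| wins ties);
    mass-only match -> the distinct base names with an " isomer"
    suffix, "/"-joined; no mass match -> empty annotation.
    """
    if not library:
        raise ValueError("annotation library is empty")
    mass_hits = [
        (abs(neutral_mass - e.neutral_mass) / e.neutral_mass * 1e6, e)
        for e in library
        if abs(neutral_mass - e.neutral_mass) <= tol.window(e.neutral_mass)
    ]
    if not mass_hits:
        return AnnotationMatch(annotation="")
    mass_hits.sort(key=lambda t: t[0])
    rt_hits = [
        (ppm, e)
        for ppm, e in mass_hits
        if e.rt is not None and abs(rt - e.rt) <= rt_tol
    ]
    if rt_hits:
        best_ppm, best = rt_hits[0]
        return AnnotationMatch(
            annotation=best.name,
            matched=[e for _, e in rt_hits],
            rt_matched=True,
        )
    bases: list[str] = []
    for _, e in mass_hits:
        b = _base_name(e.name)
        for part in b.split("/"):
            part = _base_name(part)
            if part not in bases:
                bases.append(part)
    annotation = "/".join(f"{b} isomer" for b in bases)
    return AnnotationMatch(annotation=annotation, matched=[e for _, e in mass_hits])


def annotate_compounds(
    compounds: list[ConsensusCompound],
    library: list[ReferenceCompound] | None = None,
    tol: MassTolerance = MassTolerance(5.0),
    rt_tol: float = 0.1,
) -> list[AnnotationMatch]:
    """Vector form of :func:`annotate` over consensus compounds."""
    if library is None:
        library = reference_library()
    return [annotate(c.neutral_mass, c.rt, library, tol, rt_tol) for c in compounds]


@dataclass(frozen=True)
class InclusionEntry:
    """One precursor for the targeted-MS/MS inclusion list."""

    precursor_mz: float
    rt_center: float
    rt_window: float
    collision_energies: tuple[float, ...] = DEFAULT_COLLISION_ENERGIES

    def __post_init__(self) -> None:
        if self.rt_window <= 0:
            raise ValueError("rt_window must be > 0")

    @property
    def rt_start(self) -> float:
        return self.rt_center - self.rt_window

    @property
    def rt_end(self) -> float:
        return self.rt_center + self.rt_window


def build_inclusion_list(
    selected: list[ConsensusCompound],
    rt_window: float = DEFAULT_RT_WINDOW,
    adduct: str = "[M+H]+",
    scan_range: tuple[float, float] = SCAN_RANGE,
    collision_energies: tuple[float, ...] = DEFAULT_COLLISION_ENERGIES,
) -> list[InclusionEntry]:
    """Targeted-MS/MS inclusion list for the selected compounds.

    One entry per compound at its [M+H]+ m/z; entries outside the
    instrument scan range are dropped with a warning; duplicates (same
    m/z within 5 ppm with overlapping RT windows) are merged; output
    sorted by RT.
    """
    entries: list[InclusionEntry] = []
    for c in selected:
        mz = mz_from_neutral(c.neutral_mass, adduct)
        if not (scan_range[0] <= mz <= scan_range[1]):
            logger.warning(
                "precursor m/z %.4f of %s outside scan range %s; dropped",
                mz, c.compound_id, scan_range,
            )
            continue
        dup = None
        for e in entries:
            if (
                abs(e.precursor_mz - mz) / mz * 1e6 <= 5.0
                and abs(e.rt_center - c.rt) <= 2 * rt_window
            ):
                dup = e
                break
        if dup is None:
            entries.append(
                InclusionEntry(mz, float(c.rt), rt_window, collision_energies)
            )
    entries.sort(key=lambda e: e.rt_center)
    return entries


def inclusion_table(entries: list[InclusionEntry]) -> pd.DataFrame:
    """Vendor-neutral CSV layout: mz, rt_start, rt_end, collision_energies."""
    return pd.DataFrame(
        [
            {
                "mz": e.precursor_mz,
                "rt_start": e.rt_start,
                "rt_end": e.rt_end,
                "collision_energies": ";".join(
                    f"{ce:g}" for ce in e.collision_energies
                ),
            }
            for e in entries
        ]
    )
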