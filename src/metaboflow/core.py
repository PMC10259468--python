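"""Data model and I/O for aligned LC-MS feature tables.

The quantitative backbone of every analysis in this package is a
:class:`FeatureTable`: an ions x samples matrix of integrated peak areas
together with a sample metadata table.  Ions are identified by the
``MxxxTyyy`` convention emitted by common peak-alignment software, where
``xxx`` is the mass-to-charge ratio (a.m.u.) and ``yyy`` the retention
time in seconds.  Because positive- and negative-mode datasets are
aligned separately and merged afterwards, identifiers are unique only
within an ionization mode; merged tables disambiguate them with a
``_pos`` / ``_neg`` suffix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IonID",
    "FeatureTable",
    "StudyDesign",
    "DesignReport",
    "IonParseError",
    "parse_ion_id",
    "format_ion_id",
    "read_feature_table",
    "write_feature_table",
    "validate_study_design",
    "DIETS",
    "SAMPLE_KINDS",
    "MZ_RANGE",
]

#: The four fruit diets of the reference study design, in canonical
#: (alphabetical) order.  All group orderings in this package follow it.
DIETS = ("blackcurrant", "cherry", "cranberry", "strawberry")

SAMPLE_KINDS = ("fruit", "fly", "control_fly", "blank")

#: Acquisition m/z scan range (a.m.u.) used when validation is enabled.
MZ_RANGE = (95.0, 1200.0)

_ION_RE = re.compile(r"^M(\d+(?:\.\d+)?)T(\d+(?:\.\d+)?)(?:_(pos|neg))?$")

_META_COLUMNS = ["sample_id", "kind", "diet", "generation", "replicate"]


class IonParseError(ValueError):
    """Raised when an ion identifier does not follow ``MxxxTyyy``."""


@dataclass(frozen=True)
class IonID:
    """An LC-MS feature: (m/z, retention time, ionization mode)."""

    mz: float
    rt: float
    mode: str | None = None  # "pos", "neg" or None when unambiguous

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"m/z must be positive, got {self.mz}")
        if self.rt < 0:
            raise ValueError(f"retention time must be non-negative, got {self.rt}")
        if self.mode not in (None, "pos", "neg"):
            raise ValueError(f"mode must be 'pos', 'neg' or None, got {self.mode!r}")

    def in_scan_range(self, mz_range: tuple[float, float] = MZ_RANGE) -> bool:
        return mz_range[0] <= self.mz <= mz_range[1]


def _num(x: float) -> str:
    # shortest positional (never scientific) decimal that round-trips
    s = np.format_float_positional(float(x), unique=True, trim="-")
    return s if s else "0"


def format_ion_id(ion: IonID) -> str:
    """Format an :class:`IonID` as ``MxxxTyyy`` (plus mode suffix if set)."""
    s = f"M{_num(ion.mz)}T{_num(ion.rt)}"
    if ion.mode is not None:
        s += f"_{ion.mode}"
    return s


def parse_ion_id(text: str, mode: str | None = None, *, validate_mz: bool = False) -> IonID:
    """Parse an ``MxxxTyyy[_pos|_neg]`` identifier.

    Parameters
    ----------
    text:
        The identifier string.
    mode:
        Ionization mode to attach when the identifier carries no suffix.
        A suffix in ``text`` takes precedence; a conflicting explicit
        ``mode`` is an error.
    validate_mz:
        If true, require m/z within the acquisition scan range.
    """
    if not text:
        raise IonParseError("empty ion identifier")
    m = _ION_RE.match(text)
    if m is None:
        raise IonParseError(f"malformed ion identifier {text!r}: expected MxxxTyyy[_pos|_neg]")
    mz, rt, suffix = float(m.group(1)), float(m.group(2)), m.group(3)
    if suffix is not None and mode is not None and suffix != mode:
        raise IonParseError(f"mode suffix of {text!r} conflicts with mode={mode!r}")
    ion = IonID(mz=mz, rt=rt, mode=suffix if suffix is not None else mode)
    if validate_mz and not ion.in_scan_range():
        raise IonParseError(f"m/z {mz} outside acquisition range {MZ_RANGE}")
    return ion


def _normalise_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing columns: {missing}")
    meta = meta[_META_COLUMNS]
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dups = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicated sample ids in metadata: {dups}")
    bad_kind = set(meta["kind"]) - set(SAMPLE_KINDS)
    if bad_kind:
        raise ValueError(f"unknown sample kinds: {sorted(bad_kind)}")
    meta["diet"] = meta["diet"].where(meta["diet"].notna(), None)
    meta["diet"] = meta["diet"].replace({"none": None, "": None})
    gen = pd.to_numeric(meta["generation"], errors="coerce")
    meta["generation"] = gen.astype("Int64")
    meta["replicate"] = pd.to_numeric(meta["replicate"]).astype(int)
    return meta.set_index("sample_id", drop=False)


@dataclass
class FeatureTable:
    """Ions x samples peak-area matrix with sample metadata.

    ``areas`` is indexed by ion identifier strings (``MxxxTyyy`` with an
    optional mode suffix); its columns are sample ids matching the
    ``sample_id`` index of ``samples``.  Absent peaks are stored as 0,
    encoding below-detection; cells are never missing.
    """

    areas: pd.DataFrame
    samples: pd.DataFrame
    modes: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        self.samples = _normalise_metadata(self.samples.reset_index(drop=True))
        areas = self.areas.copy()
        areas.index = areas.index.astype(str)
        areas.columns = areas.columns.astype(str)
        if set(areas.columns) != set(self.samples.index):
            orphans = sorted(set(areas.columns) ^ set(self.samples.index))
            raise ValueError(f"sample ids in matrix and metadata differ: {orphans}")
        areas = areas[list(self.samples.index)]
        try:
            areas = areas.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric peak area: {exc}") from exc
        areas = areas.fillna(0.0)
        if self.modes is None:
            modes = areas.index.to_series().map(self._suffix_mode)
        else:
            modes = self.modes.reindex(areas.index)
        if areas.index.duplicated().any():
            # duplicate ids are allowed only across modes, never within one
            per_mode = pd.DataFrame({"ion": areas.index, "mode": modes.fillna("?").values})
            counts = per_mode.groupby(["ion", "mode"]).size()
            bad = sorted({i for (i, _m), c in counts.items() if c > 1})
            if bad:
                raise ValueError(f"duplicated ion ids within a mode: {bad[:10]}")
        self.areas = areas
        self.modes = modes

    @staticmethod
    def _suffix_mode(ion_id: str) -> str | None:
        if ion_id.endswith("_pos"):
            return "pos"
        if ion_id.endswith("_neg"):
            return "neg"
        return None

    # -- convenience ---------------------------------------------------
    @property
    def n_ions(self) -> int:
        return self.areas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.areas.shape[1]

    def sample_ids(self, kind: str | None = None, diet: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if kind is not None:
            mask &= self.samples["kind"] == kind
        if diet is not None:
            mask &= self.samples["diet"] == diet
        return list(self.samples.index[mask])

    def subset_samples(self, sample_ids: list[str]) -> "FeatureTable":
        return FeatureTable(
            areas=self.areas[sample_ids],
            samples=self.samples.loc[sample_ids].reset_index(drop=True),
            modes=self.modes,
        )

    def subset_ions(self, ion_ids) -> "FeatureTable":
        return FeatureTable(
            areas=self.areas.loc[ion_ids],
            samples=self.samples.reset_index(drop=True),
            modes=self.modes,
        )

    def split_kinds(self) -> dict[str, "FeatureTable"]:
        """Split the integral table into per-kind tables (fruit/fly/...)."""
        out = {}
        for kind in SAMPLE_KINDS:
            ids = self.sample_ids(kind=kind)
            if ids:
                out[kind] = self.subset_samples(ids)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.areas.equals(other.areas)
            and self.samples.reset_index(drop=True).equals(other.samples.reset_index(drop=True))
        )


def read_feature_table(table_path, metadata_path) -> FeatureTable:
    """Read a feature table CSV/TSV and its sample metadata TSV.

    The table's first column must be ``ion_id``; an optional ``mode``
    column carries the ionization mode; every remaining column is a
    sample id that must appear in the metadata.  Absent cells are filled
    with 0.
    """
    sep = "\t" if str(table_path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(table_path, sep=sep)
    if raw.columns[0] != "ion_id":
        raise ValueError(f"first column must be 'ion_id', got {raw.columns[0]!r}")
    raw = raw.set_index("ion_id")
    modes = None
    if "mode" in raw.columns:
        modes = raw.pop("mode")
    meta = pd.read_csv(metadata_path, sep="\t")
    table_samples = set(map(str, raw.columns))
    meta_samples = set(map(str, meta["sample_id"]))
    orphans = sorted(table_samples - meta_samples)
    if orphans:
        raise ValueError(f"samples missing from metadata: {orphans}")
    meta = meta[meta["sample_id"].astype(str).isin(table_samples)]
    return FeatureTable(areas=raw, samples=meta, modes=modes)


def write_feature_table(table: FeatureTable, table_path, metadata_path) -> None:
    """Write a feature table (ions as rows) and metadata alongside it."""
    sep = "\t" if str(table_path).endswith((".tsv", ".txt")) else ","
    out = table.areas.copy()
    out.insert(0, "mode", table.modes.values if table.modes is not None else None)
    if out["mode"].isna().all():
        out = out.drop(columns="mode")
    out.index.name = "ion_id"
    out.to_csv(table_path, sep=sep)
    meta = table.samples.copy()
    meta["diet"] = meta["diet"].fillna("none")
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """Declared layout of a diet/consumer metabolome experiment.

    The reference design is 4 fruits x 3 puree replicates, fly pools for
    4 diets x 2 generations x 3 replicates except blackcurrant (a single
    generation, 3 samples), control flies for each generation, and blank
    injections.
    """

    diets: tuple[str, ...] = DIETS
    fruit_reps: int = 3
    fly_generations: tuple[int, ...] = (1, 2, 2, 2)  # per diet, aligned to `diets`
    fly_reps: int = 3
    has_controls: bool = True
    has_blank: bool = True

    def __post_init__(self) -> None:
        if not self.diets:
            raise ValueError("diets must be non-empty")
        if len(self.fly_generations) != len(self.diets):
            raise ValueError("fly_generations must align with diets")
        if self.fruit_reps <= 0 or self.fly_reps <= 0 or any(g <= 0 for g in self.fly_generations):
            raise ValueError("design counts must be strictly positive")

    @property
    def n_generations(self) -> int:
        return max(self.fly_generations)

    def generations_for(self, diet: str) -> range:
        return range(1, self.fly_generations[self.diets.index(diet)] + 1)


@dataclass
class DesignReport:
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_study_design(table: FeatureTable, design: StudyDesign) -> DesignReport:
    """Compare the samples of a table against a declared study design.

    Returns a report listing missing or unexpected sample cells and
    duplicated (kind, diet, generation, replicate) combinations; it never
    raises on mismatch.
    """
    violations: list[str] = []
    meta = table.samples

    key_cols = ["kind", "diet", "generation", "replicate"]
    keys = meta[key_cols].astype(object).apply(tuple, axis=1)
    for key, count in keys.value_counts().items():
        if count > 1:
            violations.append(f"duplicate sample cell {key} ({count} samples)")

    def expect(kind, diet, generation, n_expected):
        sel = meta[meta["kind"] == kind]
        if diet is not None:
            sel = sel[sel["diet"] == diet]
        else:
            sel = sel[sel["diet"].isna()]
        if generation is not None:
            sel = sel[sel["generation"] == generation]
        n = len(sel)
        if n < n_expected:
            violations.append(
                f"missing samples: kind={kind} diet={diet} generation={generation}: "
                f"expected {n_expected}, found {n}"
            )
        elif n > n_expected:
            violations.append(
                f"extra samples: kind={kind} diet={diet} generation={generation}: "
                f"expected {n_expected}, found {n}"
            )

    for diet in design.diets:
        expect("fruit", diet, None, design.fruit_reps)
        for g in design.generations_for(diet):
            expect("fly", diet, g, design.fly_reps)
    if design.has_controls:
        for g in range(1, design.n_generations + 1):
            sel = meta[(meta["kind"] == "control_fly") & (meta["generation"] == g)]
            if len(sel) == 0:
                violations.append(f"missing control_fly samples for generation {g}")
    if design.has_blank and (meta["kind"] == "blank").sum() == 0:
        violations.append("missing blank samples")

    known_diets = set(design.diets)
    for sid, row in meta.iterrows():
        if row["kind"] in ("fruit", "fly") and row["diet"] not in known_diets:
            violations.append(f"sample {sid}: diet {row['diet']!r} not in design")
        if row["kind"] in ("fruit", "blank") and pd.notna(row["generation"]):
            violations.append(f"sample {sid}: kind {row['kind']} must not carry a generation")
        if row["kind"] == "control_fly" and row["diet"] is not None:
            violations.append(f"sample {sid}: control_fly must have diet none")

    return DesignReport(violations=violations)
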