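"""Data model and I/O for chemical x assay high-throughput screening results.

The in-memory container mirrors the structure of a public HTS release such as
EPA ToxCast: a chemical library, an assay-endpoint panel, and a sparse
collection of per-pair results.  Each stored result carries a categorical hit
call and, for active pairs, the half-maximal activity concentration (AC50, in
micromolar) together with a cytotoxicity z-score -- the distance of the hit
from the chemical-specific cytotoxicity distribution, where larger values
indicate activity that is more specific (less likely a cytotoxic-burst
artifact).

Untested chemical-assay pairs are encoded by *absence*: a key that is not in
the results collection is untested.  Rows labelled ``untested`` in a CSV are
therefore dropped on load, which makes loading a file with explicit untested
rows indistinguishable from loading the same file with those rows removed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HitCall",
    "AssayEndpoint",
    "ChemicalRecord",
    "PairResult",
    "HTSMatrix",
    "CoverageStats",
    "HTSFormatError",
    "HTSValidationError",
    "load_hts_table",
    "write_hts_table",
]

HTS_COLUMNS = ["chemical_id", "chemical_name", "assay_id", "hit_call", "ac50_uM", "z_score"]


class HTSFormatError(ValueError):
    """The file does not have the expected tabular layout."""


class HTSValidationError(ValueError):
    """A row violates the data-model invariants."""


class HitCall(str, enum.Enum):
    """Categorical outcome of one chemical-assay screen."""

    UNTESTED = "untested"
    INACTIVE = "inactive"
    SINGLE_CONC = "single_conc_presumed_inactive"
    ACTIVE = "active"


#: hit calls that count as "tested" for coverage purposes
TESTED_CALLS = frozenset({HitCall.INACTIVE, HitCall.SINGLE_CONC, HitCall.ACTIVE})


@dataclass(frozen=True)
class AssayEndpoint:
    """One assay endpoint of the screening panel."""

    assay_id: str
    gene_symbol: Optional[str] = None
    platform_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.assay_id:
            raise HTSValidationError("assay_id must be nonempty")


@dataclass(frozen=True)
class ChemicalRecord:
    """One chemical of the screening library (id is a CASRN or registry token)."""

    chemical_id: str
    name: str = ""
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chemical_id:
            raise HTSValidationError("chemical_id must be nonempty")


@dataclass(frozen=True)
class PairResult:
    """One chemical-assay measurement.

    ``ac50_uM`` and ``z_score`` are required for active pairs and must be
    absent otherwise (a z-score reported on an inactive row of a real export
    is dropped by the loader rather than rejected).
    """

    chemical_id: str
    assay_id: str
    status: HitCall
    ac50_uM: Optional[float] = None
    z_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status is HitCall.ACTIVE:
            if self.ac50_uM is None or self.z_score is None:
                raise HTSValidationError(
                    f"active pair ({self.chemical_id}, {self.assay_id}) requires ac50_uM and z_score"
                )
            if not math.isfinite(self.ac50_uM) or self.ac50_uM <= 0:
                raise HTSValidationError(
                    f"ac50_uM must be positive and finite for ({self.chemical_id}, {self.assay_id}); "
                    f"got {self.ac50_uM!r}"
                )
            if not math.isfinite(self.z_score):
                raise HTSValidationError(
                    f"z_score must be finite for ({self.chemical_id}, {self.assay_id})"
                )
        else:
            if self.ac50_uM is not None or self.z_score is not None:
                raise HTSValidationError(
                    f"non-active pair ({self.chemical_id}, {self.assay_id}) must not carry "
                    "ac50_uM or z_score"
                )


@dataclass(frozen=True)
class CoverageStats:
    """Testing-coverage summary; fractions count any status except untested."""

    n_chemicals: int
    n_assays: int
    per_chemical: pd.Series  # fraction of panel assays tested, indexed by chemical_id
    per_assay: pd.Series  # fraction of library chemicals tested, indexed by assay_id


class HTSMatrix:
    """Sparse chemical x assay result collection with id registries.

    Every stored :class:`PairResult` must reference a registered chemical and
    assay, and there is at most one result per (chemical, assay) key.
    """

    def __init__(
        self,
        chemicals: Iterable[ChemicalRecord],
        assays: Iterable[AssayEndpoint],
        results: Iterable[PairResult],
    ) -> None:
        self.chemicals: dict[str, ChemicalRecord] = {}
        for chem in chemicals:
            if chem.chemical_id in self.chemicals:
                raise HTSValidationError(f"duplicate chemical_id {chem.chemical_id!r}")
            self.chemicals[chem.chemical_id] = chem
        self.assays: dict[str, AssayEndpoint] = {}
        for assay in assays:
            if assay.assay_id in self.assays:
                raise HTSValidationError(f"duplicate assay_id {assay.assay_id!r}")
            self.assays[assay.assay_id] = assay
        self.results: dict[tuple[str, str], PairResult] = {}
        for res in results:
            key = (res.chemical_id, res.assay_id)
            if res.chemical_id not in self.chemicals:
                raise HTSValidationError(f"result references unknown chemical {res.chemical_id!r}")
            if res.assay_id not in self.assays:
                raise HTSValidationError(f"result references unknown assay {res.assay_id!r}")
            if key in self.results:
                raise HTSValidationError(f"duplicate result for pair {key!r}")
            if res.status is HitCall.UNTESTED:
                # untested is encoded by absence; storing it would create two
                # representations of the same fact
                continue
            self.results[key] = res

    # -- basic introspection -------------------------------------------------

    @property
    def chemical_ids(self) -> list[str]:
        return list(self.chemicals)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.assays)

    def __len__(self) -> int:
        return len(self.results)

    def get(self, chemical_id: str, assay_id: str) -> PairResult:
        """Result for a pair; untested pairs come back as an UNTESTED result."""
        if chemical_id not in self.chemicals:
            raise KeyError(f"unknown chemical {chemical_id!r}")
        if assay_id not in self.assays:
            raise KeyError(f"unknown assay {assay_id!r}")
        res = self.results.get((chemical_id, assay_id))
        if res is None:
            return PairResult(chemical_id, assay_id, HitCall.UNTESTED)
        return res

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HTSMatrix):
            return NotImplemented
        return (
            self.chemicals == other.chemicals
            and self.assays == other.assays
            and self.results == other.results
        )

    # -- frame views ---------------------------------------------------------

    def _frame(self, value: Callable[[PairResult], float], default: float) -> pd.DataFrame:
        frame = pd.DataFrame(
            default, index=self.chemical_ids, columns=self.assay_ids, dtype=float
        )
        for (cid, aid), res in self.results.items():
            frame.at[cid, aid] = value(res)
        frame.index.name = "chemical_id"
        frame.columns.name = "assay_id"
        return frame

    def z_frame(self) -> pd.DataFrame:
        """z-scores for active pairs; NaN for untested, NaN for inactive."""
        return self._frame(
            lambda r: r.z_score if r.status is HitCall.ACTIVE else np.nan, np.nan
        )

    def status_frame(self) -> pd.DataFrame:
        """Hit-call strings per pair ("untested" for absent keys)."""
        frame = pd.DataFrame(
            HitCall.UNTESTED.value, index=self.chemical_ids, columns=self.assay_ids, dtype=object
        )
        for (cid, aid), res in self.results.items():
            frame.at[cid, aid] = res.status.value
        frame.index.name = "chemical_id"
        frame.columns.name = "assay_id"
        return frame

    # -- operations ----------------------------------------------------------

    def subset(
        self,
        chemicals: Optional[Sequence[str]] = None,
        assays: Optional[Sequence[str]] = None,
    ) -> "HTSMatrix":
        """Restrict to the requested chemicals/assays (untested stays absent)."""
        chem_ids = list(self.chemicals) if chemicals is None else list(chemicals)
        assay_ids = list(self.assays) if assays is None else list(assays)
        for cid in chem_ids:
            if cid not in self.chemicals:
                raise KeyError(f"unknown chemical {cid!r}")
        for aid in assay_ids:
            if aid not in self.assays:
                raise KeyError(f"unknown assay {aid!r}")
        chem_set, assay_set = set(chem_ids), set(assay_ids)
        return HTSMatrix(
            [self.chemicals[c] for c in chem_ids],
            [self.assays[a] for a in assay_ids],
            [
                res
                for (cid, aid), res in self.results.items()
                if cid in chem_set and aid in assay_set
            ],
        )

    def coverage_stats(self) -> CoverageStats:
        """Fraction of pairs tested, per chemical and per assay."""
        chem_counts = {cid: 0 for cid in self.chemicals}
        assay_counts = {aid: 0 for aid in self.assays}
        for cid, aid in self.results:
            chem_counts[cid] += 1
            assay_counts[aid] += 1
        n_chem, n_assay = len(self.chemicals), len(self.assays)
        per_chem = pd.Series(chem_counts, dtype=float, name="fraction_tested")
        per_assay = pd.Series(assay_counts, dtype=float, name="fraction_tested")
        per_chem = per_chem / n_assay if n_assay else per_chem
        per_assay = per_assay / n_chem if n_chem else per_assay
        return CoverageStats(n_chem, n_assay, per_chem, per_assay)


def subset(matrix: HTSMatrix, chemicals=None, assays=None) -> HTSMatrix:
    return matrix.subset(chemicals, assays)


def coverage_stats(matrix: HTSMatrix) -> CoverageStats:
    return matrix.coverage_stats()


def _parse_float(raw: object) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "":
        return None
    return float(text)


def load_hts_table(path) -> HTSMatrix:
    """Read a long-format HTS CSV into an :class:`HTSMatrix`.

    Expected header: ``chemical_id, chemical_name, assay_id, hit_call,
    ac50_uM, z_score`` (comma separated, UTF-8, "." decimal, empty string for
    missing).  Rows with ``hit_call=untested`` are dropped entirely, since
    absence encodes untested.  A z-score on an inactive row is ignored;
    an active row missing either number, a nonpositive AC50, or a duplicated
    (chemical, assay) key is an error.
    """
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [col for col in HTS_COLUMNS if col not in table.columns]
    if missing:
        raise HTSFormatError(f"missing required column(s): {', '.join(missing)}")

    chemicals: dict[str, ChemicalRecord] = {}
    assays: dict[str, AssayEndpoint] = {}
    results: list[PairResult] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in enumerate(table.itertuples(index=False), start=2):  # 1-based + header
        try:
            status = HitCall(row.hit_call)
        except ValueError as exc:
            raise HTSValidationError(f"row {idx}: unknown hit_call {row.hit_call!r}") from exc
        if status is HitCall.UNTESTED:
            continue
        cid, aid = row.chemical_id, row.assay_id
        if cid not in chemicals:
            chemicals[cid] = ChemicalRecord(cid, row.chemical_name)
        if aid not in assays:
            assays[aid] = AssayEndpoint(aid)
        key = (cid, aid)
        if key in seen:
            raise HTSValidationError(f"row {idx}: duplicate pair {key!r}")
        seen.add(key)
        try:
            ac50 = _parse_float(row.ac50_uM)
            z = _parse_float(row.z_score)
        except ValueError as exc:
            raise HTSValidationError(f"row {idx}: unparseable number: {exc}") from exc
        if status is not HitCall.ACTIVE:
            ac50, z = None, None  # permissive read: stray values on non-active rows dropped
        try:
            results.append(PairResult(cid, aid, status, ac50, z))
        except HTSValidationError as exc:
            raise HTSValidationError(f"row {idx}: {exc}") from exc
    return HTSMatrix(chemicals.values(), assays.values(), results)


def write_hts_table(matrix: HTSMatrix, path) -> None:
    """Write the stored results back to CSV (round-trips with `load_hts_table`).

    Floats are rendered with repr-level precision so values survive a
    write/load cycle exactly.
    """
    rows = []
    for (cid, aid) in sorted(matrix.results):
        res = matrix.results[(cid, aid)]
        rows.append(
            {
                "chemical_id": cid,
                "chemical_name": matrix.chemicals[cid].name,
                "assay_id": aid,
                "hit_call": res.status.value,
                "ac50_uM": "" if res.ac50_uM is None else repr(res.ac50_uM),
                "z_score": "" if res.z_score is None else repr(res.z_score),
            }
        )
    pd.DataFrame(rows, columns=HTS_COLUMNS).to_csv(path, index=False)
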