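"""Study-level data model and I/O for case-control methylation meta-analysis.

A *study* is a 2x2 table of methylated/unmethylated counts in a cancer arm
and a control arm, plus categorical covariates (country, sample type,
control type, assay method, publication year).  Studies may additionally
carry within-case *strata*: methylated/total counts for two levels of a
clinicopathological variable (FIGO stage, histology, differentiation grade,
age group).

The built-in corpus transcribes the eight eligible case-control studies of
OPCML promoter methylation in ovarian cancer (476 cases, 385 controls).
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "CorpusError",
    "StratumPair",
    "StudyRecord",
    "StudyCorpus",
    "builtin_corpus",
    "load_studies",
    "save_studies",
    "subset",
    "COUNTRIES",
    "SAMPLE_TYPES",
    "CONTROL_TYPES",
    "METHODS",
    "STRATUM_VARIABLES",
    "SUBSET_VARIABLES",
]

COUNTRIES = ("China", "Poland")
SAMPLE_TYPES = ("serum", "tissues")
CONTROL_TYPES = ("NT", "NT&BOT", "AT&NT")
METHODS = ("MSP", "CCP-based FRET", "restriction-enzyme")
STRATUM_VARIABLES = ("stage", "histology", "grade", "age")

#: covariates accepted by :func:`subset`; ``size_class`` is derived from the
#: total sample size (``"<100"`` if N < 100 else ``">=100"``).
SUBSET_VARIABLES = ("country", "sample_type", "control_type", "method", "size_class")

_STUDY_COLUMNS = [
    "study_id", "year", "country", "sample_type", "control_type", "method",
    "case_m", "case_u", "ctrl_m", "ctrl_u",
]
_STRATA_COLUMNS = [
    "study_id", "variable", "level_a", "a_m", "a_n", "level_b", "b_m", "b_n",
]


class CorpusError(ValueError):
    """Raised when study data violate the corpus schema or invariants."""


@dataclass(frozen=True)
class StratumPair:
    """Within-case counts for two levels of a clinicopathological variable.

    Counts are stored as methylated/total for each level, mirroring the
    ``33/39`` notation of the source tables.  Level A is by convention the
    risk level (stage III/IV, serous histology, poorly differentiated,
    older age group).
    """

    variable: str
    level_a_label: str
    level_b_label: str
    a_m: int
    a_n: int
    b_m: int
    b_n: int

    def __post_init__(self) -> None:
        if self.variable not in STRATUM_VARIABLES:
            raise CorpusError(
                f"unknown stratum variable {self.variable!r}; "
                f"allowed: {', '.join(STRATUM_VARIABLES)}"
            )
        for m, n, lab in ((self.a_m, self.a_n, self.level_a_label),
                          (self.b_m, self.b_n, self.level_b_label)):
            if not (0 <= m <= n):
                raise CorpusError(
                    f"stratum {self.variable}/{lab}: need 0 <= methylated "
                    f"({m}) <= total ({n})"
                )


@dataclass(frozen=True)
class StudyRecord:
    """One study's 2x2 counts plus covariates.

    ``case_m``/``case_u`` are methylated/unmethylated cases, ``ctrl_m``/
    ``ctrl_u`` the same for controls.  Multi-arm control groups of a single
    article are assumed already summed into one arm.
    """

    study_id: str
    year: int
    country: str
    sample_type: str
    control_type: str
    method: str
    case_m: int
    case_u: int
    ctrl_m: int
    ctrl_u: int
    strata: tuple[StratumPair, ...] = ()
    article_id: str | None = None

    def __post_init__(self) -> None:
        for name, val in (("case_m", self.case_m), ("case_u", self.case_u),
                          ("ctrl_m", self.ctrl_m), ("ctrl_u", self.ctrl_u)):
            if not isinstance(val, int) or isinstance(val, bool) or val < 0:
                raise CorpusError(
                    f"study {self.study_id!r}: {name} must be a non-negative "
                    f"integer, got {val!r}"
                )
        if self.case_m + self.case_u < 1 or self.ctrl_m + self.ctrl_u < 1:
            raise CorpusError(f"study {self.study_id!r}: empty arm")
        for name, val, allowed in (("country", self.country, COUNTRIES),
                                   ("sample_type", self.sample_type, SAMPLE_TYPES),
                                   ("control_type", self.control_type, CONTROL_TYPES),
                                   ("method", self.method, METHODS)):
            if val not in allowed:
                raise CorpusError(
                    f"study {self.study_id!r}: {name}={val!r} not in allowed "
                    f"levels {{{', '.join(allowed)}}}"
                )
        n_case = self.case_m + self.case_u
        for pair in self.strata:
            if pair.a_n + pair.b_n > n_case:
                raise CorpusError(
                    f"study {self.study_id!r}: {pair.variable} stratum totals "
                    f"{pair.a_n}+{pair.b_n} exceed case count {n_case}"
                )

    @property
    def n_case(self) -> int:
        return self.case_m + self.case_u

    @property
    def n_ctrl(self) -> int:
        return self.ctrl_m + self.ctrl_u

    @property
    def sample_size(self) -> int:
        return self.n_case + self.n_ctrl

    @property
    def size_class(self) -> str:
        return "<100" if self.sample_size < 100 else ">=100"

    @property
    def counts(self) -> tuple[int, int, int, int]:
        """(case_m, case_u, ctrl_m, ctrl_u)."""
        return (self.case_m, self.case_u, self.ctrl_m, self.ctrl_u)

    def covariate(self, variable: str) -> str:
        if variable not in SUBSET_VARIABLES:
            raise CorpusError(
                f"unknown covariate {variable!r}; allowed: "
                f"{', '.join(SUBSET_VARIABLES)}"
            )
        if variable == "size_class":
            return self.size_class
        return getattr(self, variable)


@dataclass(frozen=True)
class StudyCorpus:
    """An ordered, validated collection of studies.

    Order is stable and defines the deterministic ordering of every
    downstream table (forest rows, leave-one-out rows, funnel points).
    """

    records: tuple[StudyRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.study_id in seen:
                raise CorpusError(f"duplicate study_id {rec.study_id!r}")
            seen.add(rec.study_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __getitem__(self, study_id: str) -> StudyRecord:
        for rec in self.records:
            if rec.study_id == study_id:
                return rec
        raise KeyError(study_id)

    @property
    def study_ids(self) -> tuple[str, ...]:
        return tuple(r.study_id for r in self.records)

    @property
    def total_cases(self) -> int:
        return sum(r.n_case for r in self.records)

    @property
    def total_controls(self) -> int:
        return sum(r.n_ctrl for r in self.records)

    def drop(self, study_id: str) -> "StudyCorpus":
        """Corpus without one study (order otherwise preserved)."""
        if study_id not in self.study_ids:
            raise KeyError(study_id)
        return StudyCorpus(
            tuple(r for r in self.records if r.study_id != study_id),
            provenance=f"{self.provenance} (without {study_id})",
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "study_id": r.study_id, "year": r.year, "country": r.country,
                "sample_type": r.sample_type, "control_type": r.control_type,
                "method": r.method, "case_m": r.case_m, "case_u": r.case_u,
                "ctrl_m": r.ctrl_m, "ctrl_u": r.ctrl_u,
            })
        return pd.DataFrame(rows, columns=_STUDY_COLUMNS)

    def strata_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for p in r.strata:
                rows.append({
                    "study_id": r.study_id, "variable": p.variable,
                    "level_a": p.level_a_label, "a_m": p.a_m, "a_n": p.a_n,
                    "level_b": p.level_b_label, "b_m": p.b_m, "b_n": p.b_n,
                })
        return pd.DataFrame(rows, columns=_STRATA_COLUMNS)

    def digest(self) -> str:
        """SHA-256 of the canonical CSV serialization (order-sensitive)."""
        buf = io.StringIO()
        self.to_frame().to_csv(buf, index=False)
        self.strata_frame().to_csv(buf, index=False)
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()


def _records_from_frames(studies: pd.DataFrame,
                         strata: pd.DataFrame | None) -> list[StudyRecord]:
    missing = [c for c in _STUDY_COLUMNS if c not in studies.columns]
    if missing:
        raise CorpusError(f"studies table missing columns: {', '.join(missing)}")
    strata_by_id: dict[str, list[StratumPair]] = {}
    if strata is not None and len(strata):
        missing = [c for c in _STRATA_COLUMNS if c not in strata.columns]
        if missing:
            raise CorpusError(f"strata table missing columns: {', '.join(missing)}")
        for i, row in strata.iterrows():
            pair = StratumPair(
                variable=str(row["variable"]),
                level_a_label=str(row["level_a"]),
                level_b_label=str(row["level_b"]),
                a_m=int(row["a_m"]), a_n=int(row["a_n"]),
                b_m=int(row["b_m"]), b_n=int(row["b_n"]),
            )
            strata_by_id.setdefault(str(row["study_id"]), []).append(pair)
    records = []
    for i, row in studies.iterrows():
        counts = {}
        for col in ("case_m", "case_u", "ctrl_m", "ctrl_u"):
            val = row[col]
            if float(val) != int(val):
                raise CorpusError(
                    f"row {i} ({row['study_id']!r}): {col}={val!r} is not an integer"
                )
            counts[col] = int(val)
        sid = str(row["study_id"])
        records.append(StudyRecord(
            study_id=sid,
            year=int(row["year"]),
            country=str(row["country"]),
            sample_type=str(row["sample_type"]),
            control_type=str(row["control_type"]),
            method=str(row["method"]),
            strata=tuple(strata_by_id.get(sid, ())),
            article_id=str(row["article_id"]) if "article_id" in studies.columns else None,
            **counts,
        ))
    unclaimed = set(strata_by_id) - {r.study_id for r in records}
    if unclaimed:
        raise CorpusError(f"strata reference unknown study_ids: {sorted(unclaimed)}")
    return records


def builtin_corpus() -> StudyCorpus:
    """The packaged eight-study OPCML methylation corpus.

    Transcribed study characteristics: 476 ovarian cancer cases and 385
    controls over eight studies (one article contributes separate tissue
    and serum studies).  Multi-arm control groups within an article are
    summed into a single arm.  Grade strata are pre-recoded (high-grade
    serous and G3 as poorly differentiated; G1+G2 as well/moderately
    differentiated); the 41 metastatic samples of one source article are
    excluded.
    """
    pkg = resources.files("metaor.data")
    with resources.as_file(pkg / "studies.csv") as p:
        studies = pd.read_csv(p)
    with resources.as_file(pkg / "strata.csv") as p:
        strata = pd.read_csv(p)
    return StudyCorpus(tuple(_records_from_frames(studies, strata)),
                       provenance="builtin OPCML ovarian-cancer corpus (8 studies)")


def load_studies(path, strata_path=None, delimiter: str = ",") -> StudyCorpus:
    """Load a corpus from CSV file(s) following the packaged schema.

    ``path`` columns: study_id,year,country,sample_type,control_type,method,
    case_m,case_u,ctrl_m,ctrl_u (optional article_id).  ``strata_path``
    columns: study_id,variable,level_a,a_m,a_n,level_b,b_m,b_n.  Row order
    is preserved.
    """
    try:
        studies = pd.read_csv(path, sep=delimiter)
    except FileNotFoundError:
        raise CorpusError(f"studies file not found: {path}") from None
    strata = pd.read_csv(strata_path, sep=delimiter) if strata_path else None
    return StudyCorpus(tuple(_records_from_frames(studies, strata)),
                       provenance=f"loaded from {path}")


def save_studies(corpus: StudyCorpus, path, strata_path=None,
                 delimiter: str = ",") -> None:
    """Write a corpus in the same CSV dialect that :func:`load_studies` reads."""
    df = corpus.to_frame()
    if any(r.article_id for r in corpus):
        df.insert(1, "article_id", [r.article_id or "" for r in corpus])
    df.to_csv(path, index=False, sep=delimiter)
    if strata_path is not None:
        corpus.strata_frame().to_csv(strata_path, index=False, sep=delimiter)


def subset(corpus: StudyCorpus, variable: str, level: str) -> StudyCorpus:
    """Studies whose covariate ``variable`` equals ``level``, order preserved."""
    if variable not in SUBSET_VARIABLES:
        raise CorpusError(
            f"unknown covariate {variable!r}; allowed: {', '.join(SUBSET_VARIABLES)}"
        )
    observed = {r.covariate(variable) for r in corpus}
    if level not in observed:
        raise CorpusError(
            f"level {level!r} not observed for {variable!r}; "
            f"observed levels: {sorted(observed)}"
        )
    return StudyCorpus(
        tuple(r for r in corpus if r.covariate(variable) == level),
        provenance=f"{corpus.provenance} [{variable}={level}]",
    )
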