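"""Spontaneous adverse-event reports: data types, I/O, deduplication, cohort filtering.

The counting unit throughout the package is one individual safety report
(ISR): a single submission to a FAERS-like spontaneous-reporting system,
carrying the suspect/concomitant drugs, the adverse events coded as MedDRA
preferred terms (PTs), and basic demographics.  A *case* may be reported
several times (follow-up versions); deduplication keeps one report per case.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DrugEntry",
    "AEReport",
    "ReportSet",
    "DRUG_ROLES",
    "DEFAULT_LEXICON",
    "load_lexicon",
    "normalize_drug_name",
    "read_reports",
    "write_reports",
    "deduplicate",
    "filter_primary_suspect",
]

DRUG_ROLES = ("primary-suspect", "secondary-suspect", "concomitant", "interacting")

# FAERS role_cod equivalents accepted on ingestion.
_ROLE_ALIASES = {
    "ps": "primary-suspect",
    "ss": "secondary-suspect",
    "c": "concomitant",
    "i": "interacting",
    "primary-suspect": "primary-suspect",
    "secondary-suspect": "secondary-suspect",
    "concomitant": "concomitant",
    "interacting": "interacting",
}

SEX_VALUES = ("female", "male", "unknown")
OUTCOME_VALUES = ("death", "disability", "life-threatening", "hospitalization", "other")
_OUTCOME_SET = frozenset(OUTCOME_VALUES)

#: Anti-VEGF intravitreal agents: generic names with their brand-name aliases.
DEFAULT_LEXICON: dict[str, str] = {
    "ranibizumab": "ranibizumab",
    "lucentis": "ranibizumab",
    "byooviz": "ranibizumab",
    "susvimo": "ranibizumab",
    "aflibercept": "aflibercept",
    "eylea": "aflibercept",
    "zaltrap": "aflibercept",
    "brolucizumab": "brolucizumab",
    "beovu": "brolucizumab",
}

_QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")


@lru_cache(maxsize=512)
def parse_quarter(q: str) -> tuple[int, int]:
    """Parse a ``YYYYQn`` calendar-quarter string into ``(year, quarter)``."""
    m = _QUARTER_RE.match(str(q).strip())
    if not m:
        raise ValueError(f"malformed quarter {q!r}; expected YYYYQn with n in 1..4")
    return int(m.group(1)), int(m.group(2))


def quarter_key(q: str) -> int:
    """Total-order key for quarter strings (year*4 + quarter index)."""
    y, n = parse_quarter(q)
    return y * 4 + (n - 1)


def normalize_drug_name(name: str) -> str:
    """Case-fold and whitespace-normalize a reported drug name."""
    return " ".join(str(name).strip().lower().split())


def load_lexicon(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV (alias, generic) drug-name lexicon.

    Aliases and generics are normalized; each generic name maps to itself so
    generic spellings always resolve.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("alias", "generic"):
        if col not in df.columns:
            raise ValueError(f"lexicon file missing mandatory column {col!r}")
    lex: dict[str, str] = {}
    for alias, generic in zip(df["alias"], df["generic"]):
        g = normalize_drug_name(generic)
        lex[normalize_drug_name(alias)] = g
        lex.setdefault(g, g)
    return lex


@dataclass(frozen=True, slots=True)
class DrugEntry:
    """One drug mention on a report, with its reporter-assigned causal role."""

    name_raw: str
    name_normalized: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in DRUG_ROLES:
            raise ValueError(f"unknown drug role {self.role!r}; expected one of {DRUG_ROLES}")


@dataclass(slots=True)
class AEReport:
    """One individual safety report."""

    report_id: str
    case_id: str
    case_version: int
    receipt_quarter: str
    drugs: list[DrugEntry]
    reactions: list[str]
    sex: str = "unknown"
    age_years: float | None = None
    outcomes: frozenset[str] = frozenset()
    country: str = "unknown"

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if self.case_version < 1:
            raise ValueError("case_version must be >= 1")
        parse_quarter(self.receipt_quarter)
        if not self.reactions:
            raise ValueError(f"report {self.report_id}: reactions must be non-empty")
        if self.sex not in SEX_VALUES:
            raise ValueError(f"sex must be one of {SEX_VALUES}")
        if not isinstance(self.outcomes, frozenset):
            self.outcomes = frozenset(self.outcomes)
        if not self.outcomes <= _OUTCOME_SET:
            raise ValueError(f"unknown outcomes {sorted(self.outcomes - _OUTCOME_SET)}")

    def primary_suspects(self, lexicon: Mapping[str, str] | None = None) -> set[str]:
        """Normalized generic names of this report's primary-suspect drugs.

        Names absent from the lexicon are kept under their normalized spelling
        so background drugs remain distinguishable.
        """
        out = set()
        for d in self.drugs:
            if d.role == "primary-suspect":
                name = d.name_normalized
                if lexicon is not None:
                    name = lexicon.get(normalize_drug_name(name), name)
                out.add(name)
        return out


@dataclass
class ReportSet:
    """A collection of safety reports with ingestion provenance."""

    reports: list[AEReport]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.reports]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})[:5]
            raise ValueError(f"duplicate report_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)


_SIMPLE_COLUMNS = [
    "report_id", "case_id", "case_version", "quarter", "drug_name",
    "drug_role", "pt_list", "sex", "age", "outcomes", "country",
]


def _parse_role(raw: str) -> str:
    role = _ROLE_ALIASES.get(str(raw).strip().lower())
    if role is None:
        raise ValueError(f"unknown drug role {raw!r}")
    return role


def _row_to_report(row: Mapping[str, str]) -> AEReport:
    drugs = []
    names = str(row["drug_name"]).split("|")
    roles = str(row["drug_role"]).split("|")
    if len(names) != len(roles):
        raise ValueError("drug_name and drug_role pipe-lists differ in length")
    for name, role in zip(names, roles):
        if not name.strip():
            continue
        drugs.append(DrugEntry(name, normalize_drug_name(name), _parse_role(role)))
    pts = [p.strip() for p in str(row["pt_list"]).split("|") if p.strip()]
    age_raw = str(row.get("age", "")).strip().lower()
    age = None if age_raw in ("", "unknown", "nan") else float(age_raw)
    if age is not None and age < 0:
        raise ValueError("age must be non-negative")
    out_raw = str(row.get("outcomes", "")).strip()
    outcomes = frozenset(o.strip() for o in out_raw.split("|") if o.strip() and out_raw.lower() != "nan")
    sex = str(row.get("sex", "unknown")).strip().lower() or "unknown"
    if sex == "nan":
        sex = "unknown"
    country = str(row.get("country", "unknown")).strip() or "unknown"
    if country.lower() == "nan":
        country = "unknown"
    return AEReport(
        report_id=str(row["report_id"]).strip(),
        case_id=str(row["case_id"]).strip(),
        case_version=int(row["case_version"]),
        receipt_quarter=str(row["quarter"]).strip(),
        drugs=drugs,
        reactions=pts,
        sex=sex,
        age_years=age,
        outcomes=outcomes,
        country=country,
    )


def read_reports(path: str | Path, dialect: str = "simple-table") -> ReportSet:
    """Read a report file (or multi-table directory) into a :class:`ReportSet`.

    Two dialects are supported:

    ``simple-table``
        one UTF-8 TSV with columns ``report_id, case_id, case_version,
        quarter, drug_name, drug_role, pt_list, sex, age, outcomes, country``
        (drug and PT lists pipe-separated).
    ``faers-multitable``
        a directory of four TSVs — ``demo.tsv``, ``drug.tsv``, ``reac.tsv``,
        ``outc.tsv`` — joined on the ``report_id`` case key, mirroring the
        DEMO/DRUG/REAC/OUTC quarterly-file layout.

    Malformed rows (bad quarter, empty PT list, bad role) are rejected and
    counted in ``provenance["rejected_rows"]``; a missing mandatory column is
    a hard error naming the column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if dialect == "simple-table":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in _SIMPLE_COLUMNS[:7]:
            if col not in df.columns:
                raise ValueError(f"missing mandatory column {col!r} in {path}")
        rows = df.to_dict("records")
    elif dialect == "faers-multitable":
        rows = _read_multitable(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    reports: list[AEReport] = []
    rejected = 0
    errors: list[str] = []
    for row in rows:
        try:
            reports.append(_row_to_report(row))
        except (ValueError, KeyError) as exc:  # row-level rejection
            rejected += 1
            if len(errors) < 10:
                errors.append(str(exc))
    return ReportSet(
        reports,
        provenance={
            "source": str(path),
            "dialect": dialect,
            "rejected_rows": rejected,
            "rejection_examples": errors,
        },
    )


def _read_multitable(directory: Path) -> list[dict]:
    if not directory.is_dir():
        raise ValueError(f"faers-multitable dialect expects a directory, got {directory}")
    frames = {}
    mandatory = {
        "demo": ["report_id", "case_id", "case_version", "quarter"],
        "drug": ["report_id", "drug_name", "drug_role"],
        "reac": ["report_id", "pt"],
        "outc": ["report_id", "outcome"],
    }
    for name, cols in mandatory.items():
        fp = directory / f"{name}.tsv"
        if not fp.exists():
            raise FileNotFoundError(f"multitable component file missing: {fp}")
        df = pd.read_csv(fp, sep="\t", dtype=str, keep_default_na=False)
        for col in cols:
            if col not in df.columns:
                raise ValueError(f"missing mandatory column {col!r} in {fp}")
        frames[name] = df

    drug_g = {k: g for k, g in frames["drug"].groupby("report_id")}
    reac_g = {k: g for k, g in frames["reac"].groupby("report_id")}
    outc_g = {k: g for k, g in frames["outc"].groupby("report_id")}
    rows = []
    for rec in frames["demo"].to_dict("records"):
        rid = rec["report_id"]
        dg = drug_g.get(rid)
        rg = reac_g.get(rid)
        og = outc_g.get(rid)
        rows.append({
            "report_id": rid,
            "case_id": rec["case_id"],
            "case_version": rec["case_version"],
            "quarter": rec["quarter"],
            "drug_name": "|".join(dg["drug_name"]) if dg is not None else "",
            "drug_role": "|".join(dg["drug_role"]) if dg is not None else "",
            "pt_list": "|".join(rg["pt"]) if rg is not None else "",
            "sex": rec.get("sex", "unknown"),
            "age": rec.get("age", ""),
            "outcomes": "|".join(og["outcome"]) if og is not None else "",
            "country": rec.get("country", "unknown"),
        })
    return rows


def write_reports(rs: ReportSet, path: str | Path, dialect: str = "simple-table") -> None:
    """Write a ReportSet in either ingestion dialect (inverse of :func:`read_reports`)."""
    path = Path(path)
    rows = []
    for r in rs:
        rows.append({
            "report_id": r.report_id,
            "case_id": r.case_id,
            "case_version": r.case_version,
            "quarter": r.receipt_quarter,
            "drug_name": "|".join(d.name_raw for d in r.drugs),
            "drug_role": "|".join(d.role for d in r.drugs),
            "pt_list": "|".join(r.reactions),
            "sex": r.sex,
            "age": "" if r.age_years is None else r.age_years,
            "outcomes": "|".join(sorted(r.outcomes)),
            "country": r.country,
        })
    if dialect == "simple-table":
        pd.DataFrame(rows, columns=_SIMPLE_COLUMNS).to_csv(path, sep="\t", index=False)
    elif dialect == "faers-multitable":
        path.mkdir(parents=True, exist_ok=True)
        demo, drug, reac, outc = [], [], [], []
        for r in rs:
            demo.append({
                "report_id": r.report_id, "case_id": r.case_id,
                "case_version": r.case_version, "quarter": r.receipt_quarter,
                "sex": r.sex, "age": "" if r.age_years is None else r.age_years,
                "country": r.country,
            })
            for d in r.drugs:
                drug.append({"report_id": r.report_id, "drug_name": d.name_raw, "drug_role": d.role})
            for p in r.reactions:
                reac.append({"report_id": r.report_id, "pt": p})
            for o in sorted(r.outcomes):
                outc.append({"report_id": r.report_id, "outcome": o})
        pd.DataFrame(demo, columns=["report_id", "case_id", "case_version", "quarter", "sex", "age", "country"]).to_csv(path / "demo.tsv", sep="\t", index=False)
        pd.DataFrame(drug, columns=["report_id", "drug_name", "drug_role"]).to_csv(path / "drug.tsv", sep="\t", index=False)
        pd.DataFrame(reac, columns=["report_id", "pt"]).to_csv(path / "reac.tsv", sep="\t", index=False)
        pd.DataFrame(outc, columns=["report_id", "outcome"]).to_csv(path / "outc.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def deduplicate(rs: ReportSet) -> ReportSet:
    """Keep one report per case: highest version, then latest quarter, then report_id.

    Spontaneous-reporting systems receive follow-up versions of the same case;
    keeping the most recent version per case is the standard de-duplication
    before any counting.  Idempotent.
    """
    best: dict[str, AEReport] = {}
    for r in rs:
        key = (r.case_version, quarter_key(r.receipt_quarter), r.report_id)
        cur = best.get(r.case_id)
        if cur is None or key > (cur.case_version, quarter_key(cur.receipt_quarter), cur.report_id):
            best[r.case_id] = r
    survivors = [r for r in rs if best[r.case_id] is r]
    prov = dict(rs.provenance)
    prov["deduplicated"] = True
    prov["duplicates_removed"] = len(rs) - len(survivors)
    return ReportSet(survivors, provenance=prov)


def filter_primary_suspect(
    rs: ReportSet, lexicon: Mapping[str, str], drug: str
) -> ReportSet:
    """Retain reports naming ``drug`` (by any lexicon alias) as a primary suspect.

    ``drug`` must be a generic name known to the lexicon; otherwise the known
    generic names are listed in the error.
    """
    drug_n = normalize_drug_name(drug)
    known = sorted(set(lexicon.values()))
    if drug_n not in known:
        raise ValueError(f"drug {drug!r} not in lexicon; known generic names: {known}")
    kept = [r for r in rs if drug_n in r.primary_suspects(lexicon)]
    prov = dict(rs.provenance)
    prov["primary_suspect_filter"] = drug_n
    return ReportSet(kept, provenance=prov)


def config_hash(obj) -> str:
    """Short stable hash of a configuration object, for provenance stamping."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]
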