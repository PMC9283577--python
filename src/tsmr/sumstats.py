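"""Reading, validating and writing GWAS summary-statistic tables and LD matrices.

The on-disk dialect is a tab-separated, UTF-8 table with one header row and
canonical column names ``snp, chr, pos, ea, oa, eaf, beta, se, pval, n``.
Other headers are handled through a user-supplied column map.  Six columns are
mandatory (``snp, ea, oa, beta, se, pval``); chromosome, position, effect-allele
frequency and sample size are optional metadata.  Positions, when present, are
1-based.  The pipeline is SNP-only: indels and multi-allelic records are
rejected at read time, because palindrome and strand-complement logic is only
defined for single bases.

LD matrices are square TSV tables with variant IDs as both the first column
and the header row, holding pairwise r² values.
"""

from __future__ import annotations

import hashlib
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "SumStatsTable",
    "LdMatrix",
    "ReadReport",
    "SumStatsFormatError",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
    "table_checksum",
]

VALID_BASES = frozenset("ACGT")
CANONICAL_COLUMNS = ("snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n")
MANDATORY_COLUMNS = ("snp", "ea", "oa", "beta", "se", "pval")
_MISSING = {"", "NA", "NAN", "NONE", "."}


class SumStatsFormatError(ValueError):
    """A summary-statistic or LD file cannot be interpreted at all
    (missing mandatory column, non-square matrix, bad diagonal ...)."""


@dataclass
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele``; for binary traits
    it is on the log-odds scale.  ``eaf`` (effect-allele frequency) and ``n``
    (effective sample size) may be missing.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None

    def validation_error(self) -> str | None:
        """Return a reason string if any invariant is violated, else None."""
        if not self.variant_id:
            return "empty_variant_id"
        ea, oa = self.effect_allele, self.other_allele
        if ea not in VALID_BASES or oa not in VALID_BASES:
            return "indel_or_multiallelic"
        if ea == oa:
            return "identical_alleles"
        for name in ("beta", "se", "pval"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                return f"non_numeric_{name}"
        if self.se <= 0:
            return "non_positive_se"
        if not (0 < self.pval <= 1):
            return "pval_out_of_range"
        if self.pos is not None and self.pos < 1:
            return "non_positive_position"
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            return "eaf_out_of_range"
        if self.n is not None and self.n <= 0:
            return "non_positive_n"
        return None

    @property
    def is_palindromic(self) -> bool:
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass
class ReadReport:
    """Row accounting for one read: rows_in = rows_accepted + rows_rejected."""

    rows_in: int = 0
    rows_accepted: int = 0
    rejections: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def rows_rejected(self) -> int:
        return len(self.rejections)


@dataclass
class SumStatsTable:
    """An ordered, validated collection of variant associations for one trait."""

    trait_name: str
    records: list[VariantAssociation] = field(default_factory=list)
    trait_type: str = "quantitative"  # "binary" | "quantitative"
    read_report: ReadReport | None = None

    def __post_init__(self) -> None:
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate variant_id in table {self.trait_name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def get(self, variant_id: str) -> VariantAssociation:
        for r in self.records:
            if r.variant_id == variant_id:
                return r
        raise KeyError(variant_id)

    def subset(self, keep_ids: Iterable[str]) -> "SumStatsTable":
        """New table with only ``keep_ids``, original order preserved."""
        keep = set(keep_ids)
        return SumStatsTable(
            trait_name=self.trait_name,
            records=[r for r in self.records if r.variant_id in keep],
            trait_type=self.trait_type,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                dict(snp=r.variant_id, chr=r.chrom, pos=r.pos, ea=r.effect_allele,
                     oa=r.other_allele, eaf=r.eaf, beta=r.beta, se=r.se,
                     pval=r.pval, n=r.n)
            )
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _parse_float(token: str) -> float | None:
    try:
        return float(token)
    except (TypeError, ValueError):
        return None


def _fmt(value, sig: str = "%.10g") -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if not math.isfinite(value):
            return "NA"
        return sig % value
    return str(value)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "quantitative",
) -> SumStatsTable:
    """Read a summary-statistic TSV into a validated :class:`SumStatsTable`.

    ``column_map`` maps file headers to canonical names, e.g.
    ``{"rsid": "snp", "A1": "ea"}``.  Rows violating per-record invariants
    (zero SE, indel alleles, out-of-range p, duplicate id ...) are rejected,
    counted and logged in the returned table's ``read_report``; a missing
    mandatory column raises :class:`SumStatsFormatError` naming it.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rename = {str(k): v for k, v in (column_map or {}).items()}
    raw = raw.rename(columns=rename)
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise SumStatsFormatError(f"mandatory column {col!r} missing from {path.name}")

    report = ReadReport(rows_in=len(raw))
    records: list[VariantAssociation] = []
    seen: set[str] = set()
    has = {c: c in raw.columns for c in CANONICAL_COLUMNS}

    for i, row in enumerate(raw.itertuples(index=False)):
        row = dict(zip(raw.columns, row))
        vid = str(row["snp"]).strip()

        def _opt(col: str) -> str | None:
            if not has[col]:
                return None
            tok = str(row[col]).strip()
            return None if tok.upper() in _MISSING else tok

        pos_tok, n_tok, eaf_tok = _opt("pos"), _opt("n"), _opt("eaf")
        rec = VariantAssociation(
            variant_id=vid,
            effect_allele=str(row["ea"]).strip().upper(),
            other_allele=str(row["oa"]).strip().upper(),
            beta=_parse_float(row["beta"]) if str(row["beta"]).strip().upper() not in _MISSING else None,
            se=_parse_float(row["se"]) if str(row["se"]).strip().upper() not in _MISSING else None,
            pval=_parse_float(row["pval"]) if str(row["pval"]).strip().upper() not in _MISSING else None,
            chrom=_opt("chr"),
            pos=int(float(pos_tok)) if pos_tok and _parse_float(pos_tok) is not None else None,
            eaf=_parse_float(eaf_tok) if eaf_tok is not None else None,
            n=int(float(n_tok)) if n_tok and _parse_float(n_tok) is not None else None,
        )
        # float coercion failures on mandatory numerics surface as None
        if rec.beta is None or rec.se is None or rec.pval is None:
            bad = "beta" if rec.beta is None else ("se" if rec.se is None else "pval")
            report.rejections.append((i, vid, f"non_numeric_{bad}"))
            continue
        reason = rec.validation_error()
        if reason is not None:
            report.rejections.append((i, vid, reason))
            continue
        if vid in seen:
            report.rejections.append((i, vid, "duplicate_variant_id"))
            continue
        seen.add(vid)
        records.append(rec)

    report.rows_accepted = len(records)
    table = SumStatsTable(
        trait_name=trait_name or path.stem, records=records, trait_type=trait_type
    )
    table.read_report = report
    return table


def _serialize_sumstats(table: SumStatsTable, handle: io.TextIOBase) -> None:
    handle.write("\t".join(CANONICAL_COLUMNS) + "\n")
    for r in table.records:
        handle.write(
            "\t".join(
                [
                    r.variant_id,
                    r.chrom if r.chrom is not None else "NA",
                    _fmt(r.pos),
                    r.effect_allele,
                    r.other_allele,
                    _fmt(r.eaf),
                    _fmt(r.beta),
                    _fmt(r.se),
                    _fmt(r.pval),
                    _fmt(r.n),
                ]
            )
            + "\n"
        )


def write_sumstats(table: SumStatsTable, path: str | Path) -> Path:
    """Write the canonical TSV dialect; floats carry 10 significant digits so
    ``read_sumstats(write_sumstats(t))`` reproduces ``t`` field-for-field."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        _serialize_sumstats(table, fh)
    return path


def table_checksum(table: SumStatsTable) -> str:
    """SHA-256 of the canonical serialization (used in run metadata)."""
    buf = io.StringIO()
    _serialize_sumstats(table, buf)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()


@dataclass
class LdMatrix:
    """Pairwise r² between variants: symmetric, unit diagonal, values in [0,1]."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise SumStatsFormatError(
                f"LD matrix shape {self.r2.shape} does not match {k} variant ids"
            )
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("LD matrix not symmetric within 1e-8")
        if np.any(np.abs(np.diag(self.r2) - 1.0) > 1e-6):
            raise ValueError("LD matrix diagonal departs from 1 beyond 1e-6")
        if self.r2.min() < -1e-6 or self.r2.max() > 1 + 1e-6:
            raise ValueError("LD r² value outside [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def subset(self, ids: Sequence[str]) -> "LdMatrix":
        idx = [self._index[v] for v in ids]
        return LdMatrix(list(ids), self.r2[np.ix_(idx, idx)])


def read_ld_matrix(path: str | Path) -> LdMatrix:
    """Read a square LD TSV (ids as header row and first column).

    Asymmetry up to 1e-6 is repaired by averaging; anything larger, a
    non-square table, mismatched ids, an off-unit diagonal or an r² outside
    [0,1] is an error.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[0] != frame.shape[1]:
        raise SumStatsFormatError(f"LD matrix in {path.name} is not square: {frame.shape}")
    if list(frame.index.astype(str)) != list(frame.columns.astype(str)):
        raise SumStatsFormatError("LD matrix row and column variant ids differ")
    m = frame.to_numpy(dtype=float)
    asym = np.max(np.abs(m - m.T)) if m.size else 0.0
    if asym > 1e-6:
        raise ValueError(f"LD matrix asymmetric beyond tolerance ({asym:.2e} > 1e-6)")
    m = (m + m.T) / 2.0
    if m.size and np.any(np.abs(np.diag(m) - 1.0) > 1e-6):
        raise ValueError("LD matrix diagonal element departs from 1 beyond 1e-6")
    np.fill_diagonal(m, 1.0)
    if m.size and (m.min() < -1e-6 or m.max() > 1 + 1e-6):
        raise ValueError("LD r² value outside [0, 1]")
    m = np.clip(m, 0.0, 1.0)
    return LdMatrix(list(frame.index.astype(str)), m)


def write_ld_matrix(ld: LdMatrix, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids)
    frame.to_csv(path, sep="\t", float_format="%.10g")
    return path
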