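"""Reading, validating and writing GWAS summary statistics and LD tables.

The on-disk dialect is a tab-delimited file with the canonical header

    rsid  effect_allele  other_allele  eaf  beta  se  pvalue  n

and ``NA`` as the missing-value marker. ``n`` (per-record sample size) and
``eaf`` may be missing; operations that need them fail loudly rather than
impute. A ``column_map`` lets callers read files whose headers use other
names (GWAS summary formats vary widely and no single dialect dominates).

LD tables are three-column TSVs (``rsid_a  rsid_b  r2``) holding squared
correlations between variants; they are treated as symmetric and sparse,
with absent pairs meaning r² = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "GWASSummaryRecord",
    "LDTable",
    "CANONICAL_COLUMNS",
    "read_sumstats",
    "write_sumstats",
    "read_ld_table",
    "write_ld_table",
]

CANONICAL_COLUMNS = (
    "rsid",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

_VALID_ALLELES = frozenset("ACGT")
_NA = "NA"


@dataclass(frozen=True)
class GWASSummaryRecord:
    """One variant's association with one trait.

    ``beta`` is the per-effect-allele association on whatever scale the
    source GWAS used (log-enzyme units for the liver-enzyme exposures,
    outcome-SD units for adiposity outcomes); the package treats the scale
    as opaque. ``eaf`` is the effect-allele frequency; ``n`` the per-variant
    sample size. Both may be absent (``None``).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: int | None = None

    def validation_errors(self, context: str = "") -> list[str]:
        """Return all invariant violations for this record (empty if valid)."""
        where = f"{context}{self.rsid!r}"
        errs: list[str] = []
        if self.effect_allele not in _VALID_ALLELES:
            errs.append(f"{where}: effect_allele {self.effect_allele!r} is not one of A/C/G/T")
        if self.other_allele not in _VALID_ALLELES:
            errs.append(f"{where}: other_allele {self.other_allele!r} is not one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            errs.append(f"{where}: effect and other allele are identical")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            errs.append(f"{where}: eaf {self.eaf} outside (0, 1)")
        if not (self.se > 0.0) or not math.isfinite(self.se):
            errs.append(f"{where}: se {self.se} must be a finite positive number")
        if not math.isfinite(self.beta):
            errs.append(f"{where}: beta {self.beta} is not finite")
        if not (0.0 < self.pvalue <= 1.0):
            errs.append(f"{where}: pvalue {self.pvalue} outside (0, 1]")
        if self.n is not None and self.n <= 0:
            errs.append(f"{where}: n {self.n} must be a positive integer")
        return errs


def validate_records(records: Sequence[GWASSummaryRecord]) -> None:
    """Check every record and the one-row-per-rsid invariant.

    Raises :class:`ValidationError` listing *all* violations, not only the
    first, so a bad file can be fixed in one pass.
    """
    errors: list[str] = []
    seen: dict[str, int] = {}
    for i, rec in enumerate(records):
        errors.extend(rec.validation_errors(context=f"row {i + 1} "))
        if rec.rsid in seen:
            errors.append(
                f"row {i + 1} {rec.rsid!r}: duplicate of row {seen[rec.rsid] + 1}"
            )
        else:
            seen[rec.rsid] = i
    if errors:
        raise ValidationError(errors)


def _parse_float(token: str) -> float | None:
    if token == _NA or token == "":
        return None
    return float(token)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[GWASSummaryRecord]:
    """Read a tab-delimited summary-statistics file into validated records.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Optional mapping from canonical column name to the name used in the
        file, e.g. ``{"pvalue": "P", "rsid": "SNP"}``. Unmapped canonical
        names are looked up verbatim.

    Row order is preserved; alleles are upper-cased. All invariant
    violations are collected and reported together.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"summary-statistics file not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    column_map = dict(column_map or {})
    resolved: dict[str, str] = {}
    missing: list[str] = []
    for canon in CANONICAL_COLUMNS:
        actual = column_map.get(canon, canon)
        if actual in frame.columns:
            resolved[canon] = actual
        elif canon == "n":
            resolved[canon] = ""  # n column entirely absent is allowed
        else:
            missing.append(f"{canon!r} (looked for column {actual!r})")
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s): " + ", ".join(missing)
        )

    records: list[GWASSummaryRecord] = []
    parse_errors: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row_d = dict(zip(frame.columns, row))
        try:
            n_tok = row_d[resolved["n"]] if resolved["n"] else _NA
            n_val = None if n_tok in (_NA, "") else int(float(n_tok))
            records.append(
                GWASSummaryRecord(
                    rsid=row_d[resolved["rsid"]].strip(),
                    effect_allele=row_d[resolved["effect_allele"]].strip().upper(),
                    other_allele=row_d[resolved["other_allele"]].strip().upper(),
                    eaf=_parse_float(row_d[resolved["eaf"]]),
                    beta=float(row_d[resolved["beta"]]),
                    se=float(row_d[resolved["se"]]),
                    pvalue=float(row_d[resolved["pvalue"]]),
                    n=n_val,
                )
            )
        except (TypeError, ValueError) as exc:
            parse_errors.append(f"row {i + 1}: unparseable value ({exc})")
    if parse_errors:
        raise ValidationError(parse_errors)
    validate_records(records)
    return records


def write_sumstats(records: Iterable[GWASSummaryRecord], path: str | Path) -> Path:
    """Write records in the canonical TSV dialect; round-trips exactly.

    Floats are serialized with ``repr``-faithful formatting (Python's
    shortest round-trip representation), so ``read_sumstats(write_sumstats(x))``
    reproduces ``x`` bit for bit.
    """
    path = Path(path)
    lines = ["\t".join(CANONICAL_COLUMNS)]
    for rec in records:
        lines.append(
            "\t".join(
                [
                    rec.rsid,
                    rec.effect_allele,
                    rec.other_allele,
                    _NA if rec.eaf is None else repr(rec.eaf),
                    repr(rec.beta),
                    repr(rec.se),
                    repr(rec.pvalue),
                    _NA if rec.n is None else str(rec.n),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


class LDTable:
    """Symmetric sparse table of pairwise squared correlations (r²).

    ``r2(a, a)`` is implicitly 1; pairs absent from the table are treated
    as r² = 0, matching the sparse convention of clumping outputs.
    """

    def __init__(self) -> None:
        self._r2: dict[tuple[str, str], float] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValidationError(f"r2({a},{b}) = {r2} outside [0, 1]")
        if a == b:
            return
        key = self._key(a, b)
        prev = self._r2.get(key)
        if prev is not None and prev != r2:
            raise ValidationError(
                f"conflicting r2 entries for pair ({a},{b}): {prev} vs {r2}"
            )
        self._r2[key] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def partners(self, rsid: str) -> dict[str, float]:
        """All variants with a recorded r² to ``rsid``."""
        out: dict[str, float] = {}
        for (a, b), r2 in self._r2.items():
            if a == rsid:
                out[b] = r2
            elif b == rsid:
                out[a] = r2
        return out

    def __len__(self) -> int:
        return len(self._r2)

    def items(self):
        return self._r2.items()


def read_ld_table(path: str | Path) -> LDTable:
    """Read a three-column TSV (rsid_a, rsid_b, r2) into an :class:`LDTable`."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"LD table not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str})
    for col in ("rsid_a", "rsid_b", "r2"):
        if col not in frame.columns:
            raise ConfigurationError(f"{path}: LD table missing column {col!r}")
    table = LDTable()
    for row in frame.itertuples(index=False):
        table.set(row.rsid_a, row.rsid_b, float(row.r2))
    return table


def write_ld_table(table: LDTable, path: str | Path) -> Path:
    path = Path(path)
    lines = ["rsid_a\trsid_b\tr2"]
    for (a, b), r2 in sorted(table.items()):
        lines.append(f"{a}\t{b}\t{repr(r2)}")
    path.write_text("\n".join(lines) + "\n")
    return path
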