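"""Instrument selection: LD clumping, proxy substitution, exclusion sets.

Selection follows standard two-sample MR practice: keep genome-wide
significant variants, greedily clump them so that no two retained
instruments have r² above a threshold (retaining the smaller p-value),
replace instruments missing from the outcome GWAS by high-LD proxies, and
optionally remove named sets of suspected-pleiotropic variants for
sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .exceptions import ValidationError
from .sumstats import GWASSummaryRecord, LDTable

__all__ = [
    "InstrumentSet",
    "greedy_clump",
    "substitute_proxies",
    "apply_exclusions",
]


@dataclass
class InstrumentSet:
    """An ordered set of instrument rsids with per-rsid provenance.

    Provenance tags are ``selected``, ``proxy_for:<rsid>`` or
    ``excluded:<reason>``; excluded rsids stay in the provenance map (for
    the audit trail) but leave ``members``.
    """

    label: str
    members: list[str] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"instrument set {self.label!r} has duplicate members")
        for m in self.members:
            self.provenance.setdefault(m, "selected")

    @property
    def k(self) -> int:
        return len(self.members)


def greedy_clump(
    records: Sequence[GWASSummaryRecord],
    ld: LDTable | None = None,
    r2_threshold: float = 0.01,
    p_threshold: float | None = 5e-8,
    label: str = "clumped",
) -> InstrumentSet:
    """Greedy LD clumping of significant variants.

    Repeatedly takes the remaining variant with the smallest p-value and
    removes every variant with r² above ``r2_threshold`` to it. Ties on
    p-value are broken lexicographically on rsid so the result does not
    depend on input row order. ``p_threshold=None`` disables the
    significance filter (useful when the input is already a curated
    instrument list). Pairs absent from the LD table count as r² = 0.
    """
    if ld is None:
        ld = LDTable()
    if p_threshold is None:
        significant = list(records)
    else:
        significant = [r for r in records if r.pvalue < p_threshold]
    if not significant:
        warnings.warn(
            f"{label}: no variant passes p < {p_threshold}; empty instrument set",
            stacklevel=2,
        )
        return InstrumentSet(label=label)

    remaining = sorted(significant, key=lambda r: (r.pvalue, r.rsid))
    kept: list[str] = []
    while remaining:
        index = remaining[0]
        kept.append(index.rsid)
        remaining = [
            r for r in remaining[1:] if ld.r2(index.rsid, r.rsid) <= r2_threshold
        ]
    return InstrumentSet(
        label=label, members=kept, provenance={m: "selected" for m in kept}
    )


def substitute_proxies(
    instruments: InstrumentSet,
    available_in_outcome: Iterable[str],
    proxies: LDTable | None = None,
    r2_min: float = 0.9,
) -> InstrumentSet:
    """Replace instruments missing from the outcome GWAS by high-LD proxies.

    Each unavailable member is replaced by its highest-r² available proxy
    with r² > ``r2_min`` (ties broken lexicographically); if none exists the
    member is dropped with provenance ``excluded:no_proxy``. The proxy's own
    summary statistics are used unchanged downstream — no effect rescaling
    by r², the usual convention at r² > 0.9. Never increases the set size.
    """
    available = set(available_in_outcome)
    proxies = proxies or LDTable()
    members: list[str] = []
    provenance = dict(instruments.provenance)
    for m in instruments.members:
        if m in available:
            members.append(m)
            continue
        candidates = [
            (r2, rsid)
            for rsid, r2 in proxies.partners(m).items()
            if rsid in available and r2 > r2_min and rsid not in members
        ]
        if candidates:
            # highest r2 wins; among equal r2 the lexicographically smallest rsid
            top = max(r2 for r2, _ in candidates)
            best = min(rsid for r2, rsid in candidates if r2 == top)
            members.append(best)
            provenance[best] = f"proxy_for:{m}"
            provenance[m] = f"excluded:replaced_by_proxy:{best}"
        else:
            provenance[m] = "excluded:no_proxy"
    return InstrumentSet(label=instruments.label, members=members, provenance=provenance)


def apply_exclusions(
    instruments: InstrumentSet,
    exclusion_list: Iterable[str],
    label: str | None = None,
    reason: str = "pleiotropy",
) -> InstrumentSet:
    """Remove a named set of rsids (sensitivity analysis).

    Excluding a variant that is not a member produces a warning, not an
    error, because exclusion lists are written against the full panel while
    the working set may already have lost members upstream.
    """
    exclusions = set(exclusion_list)
    absent = exclusions - set(instruments.members)
    if absent:
        warnings.warn(
            f"{instruments.label}: exclusion rsids not in set: {sorted(absent)}",
            stacklevel=2,
        )
    provenance = dict(instruments.provenance)
    members = []
    for m in instruments.members:
        if m in exclusions:
            provenance[m] = f"excluded:{reason}"
        else:
            members.append(m)
    return InstrumentSet(
        label=label or instruments.label, members=members, provenance=provenance
    )
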