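"""Allele harmonization of exposure/outcome summary-statistic pairs.

Two GWAS report the same variant on arbitrary allele codings: the effect
allele may be the other study's non-effect allele (allele swap, which
negates the beta and inverts the frequency), or the alleles may be reported
on opposite DNA strands (strand flip, which relabels A<->T and C<->G but
leaves beta and frequency alone), or both. Palindromic variants (A/T, C/G)
are identical to their own strand complement, so allele labels carry no
strand information; they are oriented by comparing effect-allele
frequencies across the two studies, and dropped as ambiguous when either
frequency is too close to 0.5 for the comparison to be trustworthy.

After alignment, a retained pair whose effect-allele frequencies still
disagree by more than a threshold is dropped as likely mislabelled
("rather different allele distributions" between studies).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .exceptions import ConfigurationError, EmptySetError, HarmonizationError
from .instruments import InstrumentSet
from .sumstats import GWASSummaryRecord

__all__ = [
    "HarmonizedVariant",
    "HarmonizedSet",
    "harmonize_pair",
    "harmonize_set",
    "orient_exposure_positive",
    "COMPLEMENT",
    "is_palindromic",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default EAF band inside which a palindromic variant cannot be oriented.
DEFAULT_PALINDROMIC_EAF_BAND = (0.42, 0.58)
#: Default post-alignment |eaf_x - eaf_y| above which a pair is dropped.
DEFAULT_EAF_DISCORD_THRESHOLD = 0.20


def is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


@dataclass(frozen=True)
class HarmonizedVariant:
    """Exposure and outcome effects expressed on a common effect allele.

    ``action`` records what harmonization did: ``unchanged``,
    ``allele_swap``, ``strand_flip``, ``strand_flip_and_swap``,
    ``palindromic_aligned``, or ``dropped:<reason>``. Dropped variants keep
    their original (unaligned) statistics for the audit trail.
    """

    rsid: str
    bx: float
    sx: float
    by: float
    sy: float
    eaf_x: float | None
    eaf_y: float | None
    action: str

    @property
    def dropped(self) -> bool:
        return self.action.startswith("dropped:")


@dataclass
class HarmonizedSet:
    """Retained harmonized variants plus a complete audit of all actions."""

    variants: list[HarmonizedVariant] = field(default_factory=list)
    audit: list[tuple[str, str]] = field(default_factory=list)  # (rsid, action)

    @property
    def k(self) -> int:
        return len(self.variants)

    def arrays(self):
        """(bx, sx, by, sy) as float lists, in retained order."""
        bx = [v.bx for v in self.variants]
        sx = [v.sx for v in self.variants]
        by = [v.by for v in self.variants]
        sy = [v.sy for v in self.variants]
        return bx, sx, by, sy

    def drop_reasons(self) -> list[tuple[str, str]]:
        return [(r, a) for r, a in self.audit if a.startswith("dropped:")]


def harmonize_pair(
    x: GWASSummaryRecord,
    y: GWASSummaryRecord,
    palindromic_eaf_band: tuple[float, float] = DEFAULT_PALINDROMIC_EAF_BAND,
    eaf_discord_threshold: float = DEFAULT_EAF_DISCORD_THRESHOLD,
) -> HarmonizedVariant:
    """Align one exposure/outcome record pair on the exposure's effect allele.

    Resolution order: identical allele pair -> unchanged; swapped pair ->
    negate the outcome beta and invert its EAF; strand-complement pair ->
    relabel, then as above; palindromic pair -> orient by EAF concordance
    (both frequencies on the same side of 0.5), dropping variants whose EAF
    falls inside ``palindromic_eaf_band`` on either side or is missing.
    Finally, any retained pair with |eaf_x - eaf_y| above
    ``eaf_discord_threshold`` is dropped as discordant.
    """
    if x.rsid != y.rsid:
        raise HarmonizationError(
            f"cannot harmonize different variants: {x.rsid!r} vs {y.rsid!r}"
        )
    ax = (x.effect_allele, x.other_allele)
    ay = (y.effect_allele, y.other_allele)
    by, eaf_y = y.beta, y.eaf

    def dropped(reason: str) -> HarmonizedVariant:
        return HarmonizedVariant(
            rsid=x.rsid, bx=x.beta, sx=x.se, by=y.beta, sy=y.se,
            eaf_x=x.eaf, eaf_y=y.eaf, action=f"dropped:{reason}",
        )

    if is_palindromic(*ax):
        # For palindromic variants labels are strand-ambiguous: alignment
        # rests entirely on allele frequency.
        if set(ay) != set(ax):
            return dropped("allele_mismatch")
        if x.eaf is None or y.eaf is None:
            return dropped("ambiguous_palindrome")
        lo, hi = palindromic_eaf_band
        if lo <= x.eaf <= hi or lo <= y.eaf <= hi:
            return dropped("ambiguous_palindrome")
        action = "palindromic_aligned"
        if (x.eaf < 0.5) != (y.eaf < 0.5):
            by = -by
            eaf_y = 1.0 - y.eaf
    else:
        swapped = (ax[1], ax[0])
        cy = (COMPLEMENT[ay[0]], COMPLEMENT[ay[1]])
        if ay == ax:
            action = "unchanged"
        elif ay == swapped:
            action = "allele_swap"
            by = -by
            eaf_y = None if y.eaf is None else 1.0 - y.eaf
        elif cy == ax:
            action = "strand_flip"
        elif cy == swapped:
            action = "strand_flip_and_swap"
            by = -by
            eaf_y = None if y.eaf is None else 1.0 - y.eaf
        else:
            return dropped("allele_mismatch")

    hv = HarmonizedVariant(
        rsid=x.rsid, bx=x.beta, sx=x.se, by=by, sy=y.se,
        eaf_x=x.eaf, eaf_y=eaf_y, action=action,
    )
    if (
        hv.eaf_x is not None
        and hv.eaf_y is not None
        and abs(hv.eaf_x - hv.eaf_y) > eaf_discord_threshold
    ):
        return dropped("eaf_discordant")
    return hv


def harmonize_set(
    exposure_records: Sequence[GWASSummaryRecord],
    outcome_records: Sequence[GWASSummaryRecord],
    instruments: InstrumentSet,
    palindromic_eaf_band: tuple[float, float] = DEFAULT_PALINDROMIC_EAF_BAND,
    eaf_discord_threshold: float = DEFAULT_EAF_DISCORD_THRESHOLD,
) -> HarmonizedSet:
    """Harmonize every instrument, keeping a complete audit log.

    Every instrument must be present in the exposure records (proxy
    substitution happens upstream, on the instrument set). Instruments
    absent from the outcome records are dropped as ``not_in_outcome``. An
    empty retained set is an error that names every drop reason.
    """
    exp = {r.rsid: r for r in exposure_records}
    out = {r.rsid: r for r in outcome_records}
    result = HarmonizedSet()
    for rsid in instruments.members:
        if rsid not in exp:
            raise ConfigurationError(
                f"instrument {rsid!r} missing from exposure records"
            )
        if rsid not in out:
            result.audit.append((rsid, "dropped:not_in_outcome"))
            continue
        hv = harmonize_pair(
            exp[rsid],
            out[rsid],
            palindromic_eaf_band=palindromic_eaf_band,
            eaf_discord_threshold=eaf_discord_threshold,
        )
        result.audit.append((rsid, hv.action))
        if not hv.dropped:
            result.variants.append(hv)
    if not result.variants:
        reasons = "; ".join(f"{r}: {a}" for r, a in result.audit) or "no instruments"
        raise EmptySetError(f"no variants survived harmonization ({reasons})")
    return result


def orient_exposure_positive(hset: HarmonizedSet) -> HarmonizedSet:
    """Jointly negate (bx, by) so every exposure beta is non-negative.

    Wald ratios are untouched by the joint negation, but MR-Egger's slope
    and intercept are not orientation-invariant, so this canonical
    orientation is applied before Egger regression. Variants with exactly
    zero exposure beta have an undefined ratio and are dropped.
    """
    out = HarmonizedSet(audit=list(hset.audit))
    for v in hset.variants:
        if v.bx == 0.0:
            out.audit.append((v.rsid, "dropped:zero_exposure_beta"))
            continue
        if v.bx < 0.0:
            v = replace(v, bx=-v.bx, by=-v.by,
                        eaf_x=None if v.eaf_x is None else 1.0 - v.eaf_x,
                        eaf_y=None if v.eaf_y is None else 1.0 - v.eaf_y)
        out.variants.append(v)
    if not out.variants:
        raise EmptySetError("orientation left no variants (all exposure betas zero)")
    return out
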