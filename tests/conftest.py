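import pytest

from twosample_mr import GWASSummaryRecord, HarmonizedSet, HarmonizedVariant


def make_record(
    rsid="rs1",
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.05,
    se=0.01,
    pvalue=1e-9,
    n=10_000,
):
    return GWASSummaryRecord(
        rsid=rsid,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
    )


def make_harmonized(rows, actions=None):
    """Build a HarmonizedSet from (bx, sx, by, sy) tuples."""
    variants = [
        HarmonizedVariant(
            rsid=f"rs{i + 1}",
            bx=bx,
            sx=sx,
            by=by,
            sy=sy,
            eaf_x=0.3,
            eaf_y=0.3,
            action="unchanged",
        )
        for i, (bx, sx, by, sy) in enumerate(rows)
    ]
    return HarmonizedSet(variants=variants, audit=[(v.rsid, v.action) for v in variants])


@pytest.fixture
def toy_set():
    """Three-variant set with hand-checkable weights."""
    return make_harmonized(
        [
            (0.1, 0.005, 0.02, 0.01),
            (0.2, 0.005, 0.03, 0.01),
            (0.15, 0.005, 0.04, 0.02),
        ]
    )
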