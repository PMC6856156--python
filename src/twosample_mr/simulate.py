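"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generative model mirrors the standard two-sample MR setting: per
variant j with effect-allele frequency p_j, the instrument effect on the
(unit-variance) exposure is γ_j, the direct (pleiotropic) effect on the
outcome is α_j, and the true causal effect is θ. Observed summary
statistics are

    β̂x_j ~ N(γ_j,        sx_j),   sx_j = 1/sqrt(2 p_j (1−p_j) n_exposure)
    β̂y_j ~ N(θ·γ_j + α_j, sy_j),  sy_j = 1/sqrt(2 p_j (1−p_j) n_outcome)

— the usual standard-error approximation for a unit-variance trait, which
gives realistic weight heterogeneity across allele frequencies. Instruments
are independent by construction, matching post-clumping data. Pleiotropy is
``none`` (α = 0), ``balanced`` (zero-mean α) or ``directional`` (non-zero
mean α, satisfying InSIDE because α is drawn independently of γ).

``scramble_alleles`` produces allele-coding adversarial copies (swaps,
strand flips, ambiguous palindromes) to exercise harmonization, and
``make_liver_enzyme_fixture`` builds three liver-enzyme-like exposure panels
(k = 4 / 14 / 26 explaining r² ≈ 0.001 / 0.035 / 0.019 of the exposure in a
GWAS of 61,089) against a BMI-like outcome GWAS of 681,275, including a
missing outcome variant with and without a usable proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .harmonize import COMPLEMENT, HarmonizedSet, harmonize_set, is_palindromic
from .instruments import InstrumentSet
from .sumstats import GWASSummaryRecord, LDTable, write_ld_table, write_sumstats

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_two_sample_study",
    "scramble_alleles",
    "LiverEnzymeFixture",
    "make_liver_enzyme_fixture",
    "write_liver_enzyme_workspace",
]

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

_P_FLOOR = 1e-300  # keep p-values inside (0, 1] under extreme z-scores


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated two-sample study.

    Defaults describe a well-powered benchmark: 50 independent instruments,
    exposure and outcome GWAS of 100,000 each, a causal effect of 0.2
    outcome SD per unit exposure, instrument effects |N(0.05, 0.02)| (the
    positive sign convention pushes all orientation handling downstream),
    allele frequencies uniform on (0.05, 0.95), no pleiotropy, and 15% of
    variants palindromic.
    """

    k: int = 50
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    theta: float = 0.2
    gamma_mean: float = 0.05
    gamma_sd: float = 0.02
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    eaf_low: float = 0.05
    eaf_high: float = 0.95
    eaf_cross_study_sd: float = 0.005
    palindromic_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        errs = []
        if self.k < 1:
            errs.append(f"k={self.k} must be >= 1")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            errs.append("sample sizes must be positive")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            errs.append(f"unknown pleiotropy model {self.pleiotropy!r}")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            errs.append("palindromic_fraction outside [0, 1]")
        if self.gamma_sd < 0 or self.pleiotropy_sd < 0:
            errs.append("sd parameters must be >= 0")
        if not (0.0 < self.eaf_low < self.eaf_high < 1.0):
            errs.append("eaf bounds must satisfy 0 < low < high < 1")
        if errs:
            raise ValidationError(errs)


@dataclass
class SyntheticStudy:
    """Simulated exposure and outcome records plus the generating truth."""

    exposure: list[GWASSummaryRecord]
    outcome: list[GWASSummaryRecord]
    theta: float
    gamma: tuple[float, ...]
    alpha: tuple[float, ...]
    seed: int
    config: SimulationConfig | None = None

    def instrument_set(self, label: str = "simulated") -> InstrumentSet:
        return InstrumentSet(label=label, members=[r.rsid for r in self.exposure])

    def to_harmonized(self, **kwargs) -> HarmonizedSet:
        """Harmonize the study's records with default (or given) thresholds."""
        return harmonize_set(
            self.exposure, self.outcome, self.instrument_set(), **kwargs
        )


def _se(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return np.clip(2.0 * norm.sf(np.abs(beta / se)), _P_FLOOR, 1.0)


def _records(
    rsids: Sequence[str],
    alleles: Sequence[tuple[str, str]],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
) -> list[GWASSummaryRecord]:
    pvals = _pvalues(beta, se)
    return [
        GWASSummaryRecord(
            rsid=rsids[j],
            effect_allele=alleles[j][0],
            other_allele=alleles[j][1],
            eaf=float(eaf[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pvalue=float(pvals[j]),
            n=n,
        )
        for j in range(len(rsids))
    ]


def simulate_two_sample_study(config: SimulationConfig) -> SyntheticStudy:
    """Draw one synthetic study; bit-reproducible from ``config.seed``.

    All randomness flows from a single seed through named sub-streams
    (allele frequencies, alleles, instrument effects, pleiotropy, noise),
    so regenerating with the same config yields identical records.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_eaf, rng_alleles, rng_gamma, rng_alpha, rng_x, rng_y = (
        np.random.default_rng(s) for s in streams
    )
    k = config.k
    eaf = rng_eaf.uniform(config.eaf_low, config.eaf_high, k)
    eaf_y = np.clip(
        eaf + rng_eaf.normal(0.0, config.eaf_cross_study_sd, k), 0.01, 0.99
    )

    palindromic = rng_alleles.random(k) < config.palindromic_fraction
    alleles = []
    for j in range(k):
        pool = _PALINDROMIC_PAIRS if palindromic[j] else _NONPALINDROMIC_PAIRS
        alleles.append(pool[rng_alleles.integers(len(pool))])

    gamma = np.abs(rng_gamma.normal(config.gamma_mean, config.gamma_sd, k))
    if config.pleiotropy == "none":
        alpha = np.zeros(k)
    else:
        mean = config.pleiotropy_mean if config.pleiotropy == "directional" else 0.0
        alpha = rng_alpha.normal(mean, config.pleiotropy_sd, k)

    sx = _se(eaf, config.n_exposure)
    sy = _se(eaf, config.n_outcome)
    bx = gamma + sx * rng_x.standard_normal(k)
    by = config.theta * gamma + alpha + sy * rng_y.standard_normal(k)

    rsids = [f"rs{1000001 + j}" for j in range(k)]
    return SyntheticStudy(
        exposure=_records(rsids, alleles, eaf, bx, sx, config.n_exposure),
        outcome=_records(rsids, alleles, eaf_y, by, sy, config.n_outcome),
        theta=config.theta,
        gamma=tuple(gamma),
        alpha=tuple(alpha),
        seed=config.seed,
        config=config,
    )


def scramble_alleles(
    study: SyntheticStudy,
    swap_probability: float = 0.5,
    flip_probability: float = 0.5,
    palindromic_ambiguity_probability: float = 0.0,
    seed: int = 0,
) -> SyntheticStudy:
    """Adversarially re-code the outcome records; the truth is unchanged.

    With the given probabilities each outcome record is allele-swapped
    (alleles exchanged, beta negated, EAF inverted) and/or strand-flipped
    (alleles complemented); palindromic records can additionally have their
    EAF pushed into the ambiguous near-0.5 zone. Harmonization must undo
    swaps and flips exactly and must drop ambiguous palindromes.
    """
    rng = np.random.default_rng(seed)
    scrambled: list[GWASSummaryRecord] = []
    for rec in study.outcome:
        ea, oa, beta, eaf = rec.effect_allele, rec.other_allele, rec.beta, rec.eaf
        if rng.random() < swap_probability:
            ea, oa = oa, ea
            beta = -beta
            eaf = None if eaf is None else 1.0 - eaf
        if rng.random() < flip_probability:
            ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
        if (
            is_palindromic(ea, oa)
            and rng.random() < palindromic_ambiguity_probability
        ):
            eaf = float(rng.uniform(0.45, 0.55))
        scrambled.append(
            replace(rec, effect_allele=ea, other_allele=oa, beta=beta, eaf=eaf)
        )
    return SyntheticStudy(
        exposure=study.exposure,
        outcome=scrambled,
        theta=study.theta,
        gamma=study.gamma,
        alpha=study.alpha,
        seed=study.seed,
        config=study.config,
    )


# ---------------------------------------------------------------------------
# Liver-enzyme-like fixture panels
# ---------------------------------------------------------------------------

#: Panel definitions: label -> (named rsids, k, target r2, true theta).
#: Named rsids are the variants the sensitivity exclusion lists refer to;
#: the remainder of each panel uses synthetic filler identifiers.
_PANELS = {
    "ALT": (["rs2954021", "rs738409", "rs6834314"], 4, 0.001, -0.17),
    "ALP": (["rs2954021", "rs281377", "rs579459"], 14, 0.035, -0.07),
    "GGT": (["rs516246", "rs1260326", "rs8038465", "rs2073398", "rs944002"], 26, 0.019, 0.04),
}

#: Sensitivity exclusion lists mirroring the full/reduced panel design.
LIVER_ENZYME_EXCLUSIONS = {
    "ALT": {
        "no_TRIB1": ["rs2954021"],
        "no_TRIB1_PNPLA3": ["rs2954021", "rs738409"],
    },
    "ALP": {
        "no_TRIB1": ["rs2954021"],
        "no_TRIB1_FUT2_ABO": ["rs2954021", "rs281377", "rs579459"],
    },
    "GGT": {
        "no_FUT2_GCKR": ["rs516246", "rs1260326"],
    },
}

FIXTURE_N_EXPOSURE = 61_089
FIXTURE_N_OUTCOME = 681_275
#: Outcome variant with no proxy above r² = 0.9 (dropped, shrinking GGT to 25).
FIXTURE_MISSING_NO_PROXY = "rs516246"
#: Outcome variant replaced by a proxy present in both GWAS.
FIXTURE_MISSING_WITH_PROXY = ("rs2073398", "rs5751901", 0.95)


@dataclass
class LiverEnzymeFixture:
    """Three exposure panels, one outcome file, proxy LD and exclusion sets."""

    exposures: dict[str, list[GWASSummaryRecord]]
    outcome: list[GWASSummaryRecord]
    ld: LDTable
    exclusion_sets: dict[str, dict[str, list[str]]]
    truth: dict[str, SyntheticStudy]
    n_exposure: int = FIXTURE_N_EXPOSURE
    n_outcome: int = FIXTURE_N_OUTCOME
    r2: dict[str, float] = field(default_factory=dict)


def _calibrated_panel(
    rsids: list[str],
    r2_target: float,
    theta: float,
    rng: np.random.Generator,
    shared: dict[str, tuple[tuple[str, str], float, GWASSummaryRecord]],
) -> SyntheticStudy:
    """One exposure panel whose observed variance explained equals the target.

    Instrument effects are drawn with a common shape and then scaled so the
    realized Σ 2p(1−p)·β̂x² hits ``r2_target`` exactly, which pins the joint
    F statistic to the value implied by (r², n, k). The scaling constant is
    the positive root of the induced quadratic — exposure noise is sampled
    first, so β̂x = γ + ε still holds exactly afterwards.
    """
    k = len(rsids)
    eaf = rng.uniform(0.05, 0.95, k)
    alleles: list[tuple[str, str]] = []
    for j, rs in enumerate(rsids):
        if rs in shared:
            alleles_j, eaf_j, _ = shared[rs]
            alleles.append(alleles_j)
            eaf[j] = eaf_j
        else:
            alleles.append(_NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))])

    g = np.maximum(np.abs(rng.normal(1.0, 0.3, k)), 0.1)
    sx = _se(eaf, FIXTURE_N_EXPOSURE)
    eps = sx * rng.standard_normal(k)
    het = 2.0 * eaf * (1.0 - eaf)
    a = float((het * g * g).sum())
    b = float(2.0 * (het * g * eps).sum())
    c0 = float((het * eps * eps).sum())
    disc = b * b - 4.0 * a * (c0 - r2_target)
    if disc <= 0:
        raise ValidationError(
            f"cannot calibrate panel to r2={r2_target}: sampling noise alone "
            f"explains {c0:.2e}"
        )
    scale = (-b + math.sqrt(disc)) / (2.0 * a)
    gamma = scale * g
    bx = gamma + eps

    sy = _se(eaf, FIXTURE_N_OUTCOME)
    by = theta * gamma + sy * rng.standard_normal(k)
    eaf_y = np.clip(eaf + rng.normal(0.0, 0.005, k), 0.01, 0.99)

    exposure = _records(rsids, alleles, eaf, bx, sx, FIXTURE_N_EXPOSURE)
    outcome = []
    for j, rs in enumerate(rsids):
        if rs in shared:
            outcome.append(shared[rs][2])
        else:
            rec = _records(
                [rs], [alleles[j]], eaf_y[j : j + 1], by[j : j + 1],
                sy[j : j + 1], FIXTURE_N_OUTCOME,
            )[0]
            outcome.append(rec)
            shared[rs] = (alleles[j], float(eaf[j]), rec)
    return SyntheticStudy(
        exposure=exposure,
        outcome=outcome,
        theta=theta,
        gamma=tuple(gamma),
        alpha=tuple(np.zeros(k)),
        seed=-1,
    )


def make_liver_enzyme_fixture(master_seed: int = 1997) -> LiverEnzymeFixture:
    """Deterministic liver-enzyme-like panels against a BMI-like outcome.

    ALT-like (k=4, r²=0.001), ALP-like (k=14, r²=0.035) and GGT-like
    (k=26, r²=0.019) exposure panels in a GWAS of 61,089, one outcome GWAS
    of 681,275. One GGT variant is absent from the outcome with no proxy
    (panel shrinks to 25); another is absent but covered by an r²=0.95 proxy
    present in both studies. A variant shared between the ALT and ALP
    panels keeps a single consistent outcome record.
    """
    seeds = np.random.SeedSequence(master_seed).spawn(len(_PANELS))
    shared: dict[str, tuple[tuple[str, str], float, GWASSummaryRecord]] = {}
    truth: dict[str, SyntheticStudy] = {}
    exposures: dict[str, list[GWASSummaryRecord]] = {}
    r2_map: dict[str, float] = {}

    for i, ((label, (named, k, r2_target, theta)), seed) in enumerate(
        zip(_PANELS.items(), seeds)
    ):
        rng = np.random.default_rng(seed)
        filler = [f"rs{900000 + 1000 * i + j}" for j in range(k - len(named))]
        rsids = named + filler
        study = _calibrated_panel(rsids, r2_target, theta, rng, shared)
        truth[label] = study
        exposures[label] = list(study.exposure)
        r2_map[label] = r2_target

    # Assemble the single outcome file from the shared registry, dropping
    # the no-proxy variant and swapping the proxied one for its proxy.
    orig, proxy, proxy_r2 = FIXTURE_MISSING_WITH_PROXY
    ld = LDTable()
    ld.set(orig, proxy, proxy_r2)

    ggt = truth["GGT"]
    orig_idx = [r.rsid for r in ggt.exposure].index(orig)
    orig_exp = ggt.exposure[orig_idx]
    orig_out = shared[orig][2]
    # The proxy exists in both GWAS with nearly identical statistics.
    proxy_exp = replace(
        orig_exp, rsid=proxy, beta=orig_exp.beta * 0.97,
        eaf=min(0.99, orig_exp.eaf + 0.01),
        pvalue=float(_pvalues(np.array([orig_exp.beta * 0.97]), np.array([orig_exp.se]))[0]),
    )
    proxy_out = replace(
        orig_out, rsid=proxy, beta=orig_out.beta * 0.97,
        eaf=min(0.99, orig_out.eaf + 0.01),
        pvalue=float(_pvalues(np.array([orig_out.beta * 0.97]), np.array([orig_out.se]))[0]),
    )
    exposures["GGT"] = exposures["GGT"] + [proxy_exp]

    outcome = [
        rec
        for rsid, (_, _, rec) in shared.items()
        if rsid not in (FIXTURE_MISSING_NO_PROXY, orig)
    ]
    outcome.append(proxy_out)

    return LiverEnzymeFixture(
        exposures=exposures,
        outcome=outcome,
        ld=ld,
        exclusion_sets={k: dict(v) for k, v in LIVER_ENZYME_EXCLUSIONS.items()},
        truth=truth,
        r2=r2_map,
    )


def write_liver_enzyme_workspace(outdir: str | Path, master_seed: int = 1997) -> Path:
    """Write the fixture as TSV files plus a ready-to-run YAML config.

    Returns the path of the config file. Regeneration from the same seed
    writes byte-identical files.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture = make_liver_enzyme_fixture(master_seed)

    exposure_entries = []
    for label, records in fixture.exposures.items():
        path = outdir / f"{label.lower()}_exposure.tsv"
        write_sumstats(records, path)
        exposure_entries.append(
            {
                "label": label,
                "path": str(path),
                "n": fixture.n_exposure,
                "r2": fixture.r2[label],
                "exclusion_sets": fixture.exclusion_sets.get(label, {}),
            }
        )
    outcome_path = outdir / "bmi_outcome.tsv"
    write_sumstats(fixture.outcome, outcome_path)
    ld_path = outdir / "ld.tsv"
    write_ld_table(fixture.ld, ld_path)

    config = {
        "exposures": exposure_entries,
        "outcomes": [
            {
                "label": "BMI",
                "path": str(outcome_path),
                "n": fixture.n_outcome,
                "stratum": "all",
            }
        ],
        "ld_table": str(ld_path),
        "p_threshold": None,  # panels are already curated instrument lists
        "seed": master_seed,
        "output_dir": str(outdir / "results"),
    }
    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path
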