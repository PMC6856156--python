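"""Configuration-driven orchestration of the full analysis grid.

One run crosses every exposure (with each of its named instrument-exclusion
sets, plus the full set) with every outcome/stratum: select instruments by
clumping, substitute proxies for variants missing from the outcome,
harmonize alleles, run the estimator suite with diagnostics, and compute
instrument strength and power. Every drop, substitution and flip is logged,
each grid cell fails independently, and the whole run is deterministic
given the seed.

Sex-stratified analyses need no special handling: a stratum is simply
another outcome entry pointing at the stratified GWAS file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .estimators import estimate_all
from .exceptions import ConfigurationError, TwoSampleMRError
from .harmonize import (
    DEFAULT_EAF_DISCORD_THRESHOLD,
    DEFAULT_PALINDROMIC_EAF_BAND,
    harmonize_set,
)
from .instruments import apply_exclusions, greedy_clump, substitute_proxies
from .strength import build_strength_report
from .sumstats import LDTable, read_ld_table, read_sumstats

__all__ = ["ExposureSpec", "OutcomeSpec", "RunConfig", "run", "power_report"]


@dataclass
class ExposureSpec:
    label: str
    path: str
    n: int | None = None
    r2: float | None = None
    column_map: dict = field(default_factory=dict)
    exclusion_sets: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class OutcomeSpec:
    label: str
    path: str
    n: int | None = None
    stratum: str = "all"
    column_map: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis grid."""

    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    ld_table: str | None = None
    p_threshold: float | None = 5e-8
    clump_r2: float = 0.01
    proxy_r2: float = 0.9
    palindromic_eaf_band: tuple[float, float] = DEFAULT_PALINDROMIC_EAF_BAND
    eaf_discord_threshold: float = DEFAULT_EAF_DISCORD_THRESHOLD
    effects_model: str = "auto"
    n_boot: int = 10_000
    seed: int = 0
    rescale: float = 1.0
    alpha: float = 0.05
    power: float = 0.80
    output_dir: str = "."

    def __post_init__(self) -> None:
        labels = [e.label for e in self.exposures] + [
            f"{o.label}/{o.stratum}" for o in self.outcomes
        ]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"duplicate labels in config: {sorted(labels)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        exposures = [ExposureSpec(**e) for e in raw.pop("exposures")]
        outcomes = [OutcomeSpec(**o) for o in raw.pop("outcomes")]
        if "palindromic_eaf_band" in raw:
            raw["palindromic_eaf_band"] = tuple(raw["palindromic_eaf_band"])
        return cls(exposures=exposures, outcomes=outcomes, **raw)


def run(config: RunConfig, write: bool = True) -> dict[str, pd.DataFrame]:
    """Execute the grid; returns results, audit and strength tables.

    Results carry one row per (exposure x outcome x instrument set x
    applicable method). A failing cell is logged and skipped; the rest of
    the grid still runs. With ``write=True`` the tables and a plain-text
    decision log are written under ``config.output_dir``.
    """
    ld = read_ld_table(config.ld_table) if config.ld_table else LDTable()
    log: list[str] = []
    results: list[pd.DataFrame] = []
    audit_rows: list[dict] = []
    strength_rows: list[dict] = []

    outcome_records = {
        (o.label, o.stratum): read_sumstats(o.path, o.column_map) for o in config.outcomes
    }
    for exposure in config.exposures:
        exp_records = read_sumstats(exposure.path, exposure.column_map)
        base = greedy_clump(
            exp_records,
            ld,
            r2_threshold=config.clump_r2,
            p_threshold=config.p_threshold,
            label=f"{exposure.label}_all",
        )
        log.append(f"{exposure.label}: clumped to {base.k} instruments")
        instrument_sets = {"all": base}
        for name, rsids in exposure.exclusion_sets.items():
            instrument_sets[name] = apply_exclusions(
                base, rsids, label=f"{exposure.label}_{name}"
            )

        for outcome in config.outcomes:
            out_records = outcome_records[(outcome.label, outcome.stratum)]
            available = {r.rsid for r in out_records} & {r.rsid for r in exp_records}
            cell = f"{exposure.label} x {outcome.label}/{outcome.stratum}"
            harmonized = {}
            for set_name, inst in instrument_sets.items():
                try:
                    with_proxies = substitute_proxies(
                        inst, available, ld, r2_min=config.proxy_r2
                    )
                    for rsid, tag in with_proxies.provenance.items():
                        if tag != "selected":
                            log.append(f"{cell} [{set_name}]: {rsid} {tag}")
                            audit_rows.append(
                                {
                                    "exposure": exposure.label,
                                    "outcome": outcome.label,
                                    "stratum": outcome.stratum,
                                    "set_label": set_name,
                                    "rsid": rsid,
                                    "action": tag,
                                }
                            )
                    hset = harmonize_set(
                        exp_records,
                        out_records,
                        with_proxies,
                        palindromic_eaf_band=config.palindromic_eaf_band,
                        eaf_discord_threshold=config.eaf_discord_threshold,
                    )
                    for rsid, action in hset.audit:
                        if action != "unchanged":
                            log.append(f"{cell} [{set_name}]: {rsid} {action}")
                        audit_rows.append(
                            {
                                "exposure": exposure.label,
                                "outcome": outcome.label,
                                "stratum": outcome.stratum,
                                "set_label": set_name,
                                "rsid": rsid,
                                "action": action,
                            }
                        )
                    harmonized[set_name] = hset
                except TwoSampleMRError as exc:
                    log.append(f"{cell} [{set_name}]: FAILED ({exc})")
            if not harmonized:
                continue
            frame = estimate_all(
                harmonized,
                effects_model=config.effects_model,
                n_boot=config.n_boot,
                seed=config.seed,
                rescale=config.rescale,
                extra_columns={
                    "exposure": exposure.label,
                    "outcome": outcome.label,
                    "stratum": outcome.stratum,
                },
            )
            results.append(frame)

            if exposure.r2 is not None and exposure.n is not None:
                report = build_strength_report(
                    r2=exposure.r2,
                    n_exposure=exposure.n,
                    k=base.k,
                    n_outcome=outcome.n,
                    alpha=config.alpha,
                    power=config.power,
                )
                strength_rows.append(
                    {
                        "exposure": exposure.label,
                        "outcome": outcome.label,
                        "stratum": outcome.stratum,
                        "k": report.k,
                        "r2": report.r2,
                        "n_exposure": report.n_exposure,
                        "n_outcome": report.n_outcome,
                        "f_stat": report.f_stat,
                        "alpha": report.alpha,
                        "power": report.power,
                        "min_detectable": report.min_detectable,
                    }
                )
            else:
                log.append(f"{cell}: strength skipped (missing n or r2)")

    tables = {
        "results": pd.concat(results, ignore_index=True) if results else pd.DataFrame(),
        "audit": pd.DataFrame(audit_rows),
        "strength": pd.DataFrame(strength_rows),
    }
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        (outdir / "run.log").write_text("\n".join(log) + "\n")
    tables["log"] = log
    return tables


def power_report(config: RunConfig) -> pd.DataFrame:
    """F statistic and minimum detectable effect per exposure-outcome pair.

    Pairs missing the exposure r²/n or the outcome n are skipped with a
    warning line in the returned frame's ``attrs['warnings']``.
    """
    rows: list[dict] = []
    warnings_: list[str] = []
    for exposure in config.exposures:
        if exposure.r2 is None or exposure.n is None:
            warnings_.append(f"{exposure.label}: skipped (missing n or r2)")
            continue
        exp_records = read_sumstats(exposure.path, exposure.column_map)
        k = greedy_clump(
            exp_records,
            read_ld_table(config.ld_table) if config.ld_table else None,
            r2_threshold=config.clump_r2,
            p_threshold=config.p_threshold,
        ).k
        for outcome in config.outcomes:
            if outcome.n is None:
                warnings_.append(
                    f"{exposure.label} x {outcome.label}: skipped (missing outcome n)"
                )
                continue
            report = build_strength_report(
                r2=exposure.r2,
                n_exposure=exposure.n,
                k=k,
                n_outcome=outcome.n,
                alpha=config.alpha,
                power=config.power,
            )
            rows.append(
                {
                    "exposure": exposure.label,
                    "outcome": outcome.label,
                    "stratum": outcome.stratum,
                    "k": report.k,
                    "r2": report.r2,
                    "f_stat": report.f_stat,
                    "min_detectable": report.min_detectable,
                }
            )
    frame = pd.DataFrame(rows)
    frame.attrs["warnings"] = warnings_
    return frame
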