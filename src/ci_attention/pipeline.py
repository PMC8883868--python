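"""End-to-end cohort runs: simulate -> reconstruct -> spectra -> statistics.

A :class:`RunConfig` bundles every stage's settings under one master seed;
per-subject and per-stage child seeds are derived from it by a fixed key
scheme, so re-running a configuration is bit-identical and adding subjects
never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cluster_stats, decoding, reconstruction, spectral, volume_conduction
from .reconstruction import FilterSpec
from .synthetic_session import (
    AUDITORY,
    EffectSpec,
    SessionConfig,
    VISUAL,
    generate_eeg_companion,
    generate_session,
    metadata_frame,
    simulate_behavior,
)

__all__ = ["RunConfig", "RunReport", "validate_config", "run_cohort"]


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of a cohort analysis run."""

    session: SessionConfig = field(default_factory=SessionConfig)
    effect: EffectSpec = field(default_factory=EffectSpec)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    fois: tuple[str, ...] = ("broadband", "theta", "alpha", "beta")
    contrast_fois: tuple[str, ...] = ("theta", "alpha", "beta")
    n_subjects: int = 16
    n_perm_cluster: int = 10_000
    n_perm_decode: int = 1000
    cluster_alpha: float = 0.05
    tail: str = "greater"
    discard_n: int | None = None  # defaults to the session's artifact prefix
    apply_filter: bool = True
    pad_mode: str = "mirror"
    run_volume_conduction: bool = True
    n_eeg_channels: int = 55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        for foi in (*self.fois, *self.contrast_fois):
            if foi not in spectral.BANDS:
                raise ValueError(f"unknown band {foi!r}")

    @property
    def effective_discard_n(self) -> int:
        return self.session.artifact_prefix_len if self.discard_n is None else self.discard_n


@dataclass
class RunReport:
    """All results of one cohort run (JSON-serialisable via ``to_dict``)."""

    config: RunConfig
    behavior: cluster_stats.BehaviorStats
    band_power: pd.DataFrame  # subject x condition x band values
    contrast_tests: dict[str, cluster_stats.ClusterTestResult]
    broadband_cluster: cluster_stats.ClusterTestResult
    decoding_results: list[decoding.DecodingResult]
    group_decoding: decoding.GroupDecodingStats
    vc: volume_conduction.BayesCorrResult | None

    def to_dict(self) -> dict:
        d = {
            "config": _config_to_mapping(self.config),
            "behavior": {
                "paired_t": self.behavior.paired_t,
                "df": self.behavior.df,
                "p": self.behavior.p,
                "d": self.behavior.d,
                "power_performance": self.behavior.power_performance,
            },
            "band_power": self.band_power.to_dict(orient="records"),
            "contrast_tests": {
                k: {
                    "p_value": v.p_value,
                    "effect_size_d": v.effect_size_d,
                    "n_permutations": v.n_permutations,
                    "cluster_masses": list(v.cluster_masses),
                }
                for k, v in {**self.contrast_tests, "broadband_cluster": self.broadband_cluster}.items()
            },
            "decoding": [
                {
                    "subject": r.subject_id,
                    "foi": r.foi,
                    "best_k": r.best_k,
                    "observed": r.observed_accuracy,
                    "chance": r.chance_level,
                    "p": r.p_value,
                }
                for r in self.decoding_results
            ],
            "group_decoding": {
                "per_foi_t": self.group_decoding.per_foi_t,
                "anova": self.group_decoding.anova.to_dict(orient="records"),
                "n_subjects_significant": self.group_decoding.n_subjects_significant,
            },
        }
        if self.vc is not None:
            d["volume_conduction"] = {
                "mean_ln_bf10": self.vc.mean_ln_bf10,
                "sd_ln_bf10": self.vc.sd_ln_bf10,
                "mean_r": float(np.mean(self.vc.r)),
                "verdicts": self.vc.verdicts,
            }
        return d


def _config_to_mapping(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["fois"] = list(config.fois)
    d["contrast_fois"] = list(config.contrast_fois)
    d["effect"]["theta_band"] = list(config.effect.theta_band)
    return d


_TOP_LEVEL_SIMPLE = {
    f.name for f in dataclasses.fields(RunConfig) if f.name not in ("session", "effect", "filter_spec")
}


def validate_config(raw: str | dict | None) -> RunConfig:
    """Parse and schema-check a YAML/JSON run configuration.

    Unknown keys are rejected; all defaults are resolved.  Errors are
    aggregated into a single ``ValueError`` listing every problem found.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    errors: list[str] = []
    session_kw = dict(raw.get("session", {}))
    effect_kw = dict(raw.get("effect", {}))
    filter_kw = dict(raw.get("filter", {}))
    other = {k: v for k, v in raw.items() if k not in ("session", "effect", "filter")}

    for name, kw, cls in (
        ("session", session_kw, SessionConfig),
        ("effect", effect_kw, EffectSpec),
        ("filter", filter_kw, FilterSpec),
    ):
        bad = set(kw) - {f.name for f in dataclasses.fields(cls)}
        if bad:
            errors.append(f"unknown {name} keys: {sorted(bad)}")
            for k in bad:
                kw.pop(k)
    bad = set(other) - _TOP_LEVEL_SIMPLE
    if bad:
        errors.append(f"unknown top-level keys: {sorted(bad)}")
        for k in bad:
            other.pop(k)
    if "theta_band" in effect_kw:
        effect_kw["theta_band"] = tuple(effect_kw["theta_band"])
    for k in ("fois", "contrast_fois"):
        if k in other:
            other[k] = tuple(other[k])

    session = effect = filt = None
    for name, build in (
        ("session", lambda: SessionConfig(**session_kw)),
        ("effect", lambda: EffectSpec(**effect_kw)),
        ("filter", lambda: FilterSpec(**filter_kw)),
    ):
        try:
            value = build()
        except (TypeError, ValueError) as exc:
            errors.append(f"{name}: {exc}")
            value = None
        if name == "session":
            session = value
        elif name == "effect":
            effect = value
        else:
            filt = value

    if errors:
        raise ValueError("invalid configuration:\n- " + "\n- ".join(errors))
    try:
        return RunConfig(session=session, effect=effect, filter_spec=filt, **other)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration:\n- {exc}") from exc


def analyze_subject(config: RunConfig, subject_index: int) -> dict:
    """Simulate and analyse one subject; returns per-subject artifacts."""
    subject_id = f"S{subject_index + 1:02d}"
    session_cfg = dataclasses.replace(config.session, seed=config.seed)
    session = generate_session(session_cfg, config.effect, subject_id=subject_id, subject_key=subject_index)
    session = simulate_behavior(session, subject_key=subject_index)
    meta = metadata_frame(session)
    kept = reconstruction.select_correct_trials(session)
    series = reconstruction.reconstruct_session(
        kept,
        discard_n=config.effective_discard_n,
        filter_spec=config.filter_spec if config.apply_filter else None,
        pad_mode=config.pad_mode,
    )
    spectra = [spectral.trial_psd(s) for s in series]
    cues = [s.cue for s in series]
    band_power = {
        (cond, band): float(
            np.mean([spectral.band_average(sp, band) for sp, c in zip(spectra, cues) if c == cond])
        )
        for cond in (AUDITORY, VISUAL)
        for band in spectral.BANDS
    }
    cond_spec = spectral.condition_average(spectra, cues)
    return {
        "subject_id": subject_id,
        "session": session,
        "metadata": meta,
        "series": series,
        "spectra": spectra,
        "cues": cues,
        "band_power": band_power,
        "condition_spectra": cond_spec,
    }


def run_cohort(config: RunConfig, n_subjects: int | None = None, outdir: str | pathlib.Path | None = None) -> RunReport:
    """Simulate and analyse a full cohort; optionally write report + tables.

    Runs every stage in order for ``n_subjects`` independent subjects
    (per-subject effect-gain jitter via the generator), then the
    group-level contrasts, decoding statistics and the volume-conduction
    check on the first subject's companion recording.
    """
    if n_subjects is None:
        n_subjects = config.n_subjects
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")

    subjects = [analyze_subject(config, i) for i in range(n_subjects)]

    # behavioural statistics: correct-trial counts per condition
    counts = np.array(
        [
            [
                int(((s["metadata"].cue == cond) & s["metadata"].response_correct).sum())
                for cond in (AUDITORY, VISUAL)
            ]
            for s in subjects
        ],
        dtype=float,
    )
    theta_power = np.array(
        [[s["band_power"][(cond, "theta")] for cond in (AUDITORY, VISUAL)] for s in subjects]
    )
    prop_correct = np.array(
        [
            [
                ((s["metadata"].cue == cond) & s["metadata"].response_correct).sum()
                / (s["metadata"].cue == cond).sum()
                for cond in (AUDITORY, VISUAL)
            ]
            for s in subjects
        ]
    )
    behavior = cluster_stats.behavior_stats(counts, theta_power, prop_correct)

    band_rows = [
        {"subject": s["subject_id"], "condition": cond, "band": band, "value": s["band_power"][(cond, band)]}
        for s in subjects
        for cond in (AUDITORY, VISUAL)
        for band in spectral.BANDS
    ]
    band_power = pd.DataFrame(band_rows)

    contrast_tests = {}
    for band in config.contrast_fois:
        a = np.array([s["band_power"][(AUDITORY, band)] for s in subjects])
        v = np.array([s["band_power"][(VISUAL, band)] for s in subjects])
        contrast_tests[band] = cluster_stats.band_permutation_test(
            a, v, n_perm=config.n_perm_cluster, tail=config.tail, band=band, seed=config.seed
        )

    spec_a = np.array([s["condition_spectra"][AUDITORY].power for s in subjects])
    spec_v = np.array([s["condition_spectra"][VISUAL].power for s in subjects])
    broadband_cluster = cluster_stats.cluster_permutation_test(
        spec_a,
        spec_v,
        n_perm=config.n_perm_cluster,
        cluster_alpha=config.cluster_alpha,
        tail=config.tail,
        band="broadband",
        seed=config.seed,
    )

    decoding_results = []
    for i, s in enumerate(subjects):
        for foi in config.fois:
            dcfg = decoding.DecodingConfig(
                foi=foi,
                n_permutations=config.n_perm_decode,
                seed=int(np.random.SeedSequence([config.seed, 7, i]).generate_state(1)[0] % 2**31),
            )
            decoding_results.append(
                decoding.decode_subject(s["spectra"], s["cues"], config=dcfg, subject_id=s["subject_id"])
            )
    group_decoding = decoding.group_stats(decoding_results)

    vc = None
    if config.run_volume_conduction:
        first = subjects[0]
        companion = generate_eeg_companion(
            first["session"], n_channels=config.n_eeg_channels, subject_key=0
        )
        ci_trials = np.stack([t.samples for t in reconstruction.reconstruct_session(first["session"], discard_n=config.effective_discard_n)])
        vc = volume_conduction.assess_volume_conduction(ci_trials, companion)

    report = RunReport(
        config=config,
        behavior=behavior,
        band_power=band_power,
        contrast_tests=contrast_tests,
        broadband_cluster=broadband_cluster,
        decoding_results=decoding_results,
        group_decoding=group_decoding,
        vc=vc,
    )
    if outdir is not None:
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
        band_power.to_csv(outdir / "band_power.tsv", sep="\t", index=False)
        group_decoding.table.to_csv(outdir / "decoding.tsv", sep="\t", index=False)
    return report
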