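"""End-to-end model-comparison pipeline.

Runs the full analysis on a (synthetic or loaded) study: builds predictor
sets, fits the full encoding model and the reduced models per subject,
derives unique-power maps for surprisal and entropy, applies smoothing and
TFCE permutation tests per group, summarizes the region of interest with
Cohen's d, and tests the entropy/surprisal power-ratio interaction between
the two groups.  Stage outputs are cached on disk keyed by a hash of the
configuration, so interrupted runs resume without refitting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mtrf import TRFBasis, cross_validate, unique_power
from .predictors import build_predictor_set, standardize
from .stats import (
    StatMap,
    paired_permutation_test,
    ratio_interaction_test,
    roi_summary,
    smooth_map,
)
from .synth import SimConfig, SimStudy, simulate_study

__all__ = ["StudyConfig", "ConfigError", "run_model_comparison", "format_report"]

KNOWN_MODELS = ("full", "minus_entropy", "minus_surprisal", "first_phoneme_split")


class ConfigError(ValueError):
    """Invalid study configuration."""


@dataclass
class StudyConfig:
    """Configuration for a model-comparison run.

    Either ``sim`` (a :class:`~cohorttrf.synth.SimConfig`) or pre-built
    study inputs must be provided.  The model list must include the full
    model; reduced models are refit from scratch, never weight-zeroed.
    """

    sim: SimConfig | None = None
    models: tuple[str, ...] = ("full", "minus_entropy", "minus_surprisal")
    k: int = 5
    step: float = 0.005
    max_iter: int = 2000
    n_permutations: int = 10000
    smoothing_sd: float = 5.0  # mm
    alpha: float = 0.05
    roi_only: bool = False  # fit only ROI sources (cheaper; maps cover ROI)
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if "full" not in self.models:
            raise ConfigError("model list must include the full model")
        unknown = [m for m in self.models if m not in KNOWN_MODELS]
        if unknown:
            raise ConfigError(f"unknown models: {unknown}")
        if self.sim is None:
            raise ConfigError("no study inputs: provide a SimConfig")
        if self.k < 3:
            raise ConfigError("cross-validation needs k >= 3")

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, dict):
                return dict(o)
            return str(o)

        fields = dataclasses.asdict(self)
        fields.pop("out_dir", None)  # output location does not affect results
        blob = json.dumps(fields, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _reduced_channels(model_name: str, channel_names: list[str]) -> list[str]:
    if model_name == "minus_entropy":
        return [c for c in channel_names if not c.startswith("entropy")]
    if model_name == "minus_surprisal":
        return [c for c in channel_names if not c.startswith("surprisal")]
    return channel_names


def _fit_power_map(ps, response, cfg: StudyConfig, basis: TRFBasis) -> np.ndarray:
    # boosting's step size is defined in standardized units
    fit = cross_validate(
        standardize(ps),
        standardize(response),
        k=cfg.k,
        step=cfg.step,
        max_iter=cfg.max_iter,
        basis=basis,
    )
    return fit.power


class _StageCache:
    def __init__(self, directory: Path | None, key: str):
        self.dir = directory
        self.key = key
        if directory is not None:
            directory.mkdir(parents=True, exist_ok=True)

    def get_or_compute(self, stage: str, fn) -> np.ndarray:
        if self.dir is None:
            return fn()
        path = self.dir / f"{self.key}_{stage}.npy"
        if path.exists():
            return np.load(path)
        value = fn()
        np.save(path, value)
        return value


def run_model_comparison(config: StudyConfig, study: SimStudy | None = None) -> dict:
    """Fit all configured models and compare them; returns the report dict.

    The report contains, per group: per-subject unique-power maps for
    surprisal and entropy, TFCE permutation-test p-values (full vs reduced
    model), ROI means and Cohen's d; across groups: the entropy/surprisal
    ratio interaction test.  When ``first_phoneme_split`` is in the model
    list, the split model is compared against the uniform full model.
    """
    config.validate()
    if study is None:
        study = simulate_study(config.sim)
    geometry = study.geometry
    basis = study.basis
    cache = _StageCache(
        Path(config.out_dir) / "cache" if config.out_dir else None,
        config.config_hash(),
    )
    source_idx = (
        np.flatnonzero(geometry.roi_mask) if config.roi_only
        else np.arange(geometry.n_sources)
    )
    roi_in_fit = (
        np.isin(source_idx, np.flatnonzero(geometry.roi_mask))
        if geometry.roi_mask is not None
        else np.ones(len(source_idx), bool)
    )

    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "models": list(config.models),
        "groups": {},
    }
    group_summaries = {}

    for gi, group in enumerate(study.groups):
        name = group.spec.name
        power: dict[str, list[np.ndarray]] = {m: [] for m in config.models}
        for si in range(group.spec.n_subjects):
            ps = group.predictor_sets[si]
            n_t = group.n_times[si]
            response = group.recordings[si][source_idx, :n_t]
            for model_name in config.models:
                if model_name == "first_phoneme_split":
                    ps_m = build_predictor_set(
                        group.sessions[si],
                        study.lexicon,
                        split_initial=True,
                        rate=study.config.rate,
                    )
                else:
                    ps_m = ps.subset(_reduced_channels(model_name, ps.names))

                def _compute(ps_m=ps_m, response=response):
                    return _fit_power_map(ps_m, response, config, basis)

                pw = cache.get_or_compute(f"g{gi}_s{si}_{model_name}", _compute)
                power[model_name].append(pw)

        power_arr = {m: np.asarray(v) for m, v in power.items()}
        group_report: dict = {"n_subjects": group.spec.n_subjects}
        deltas: dict[str, np.ndarray] = {}
        for predictor, reduced in (
            ("surprisal", "minus_surprisal"),
            ("entropy", "minus_entropy"),
        ):
            if reduced not in power_arr:
                continue
            delta = power_arr["full"] - power_arr[reduced]
            sm = smooth_map(delta, geometry_subset(geometry, source_idx), config.smoothing_sd)
            # one-tailed: does adding the predictor improve held-out power?
            test = paired_permutation_test(
                sm,
                np.zeros_like(sm),
                edges=subgraph_edges(geometry, source_idx),
                n_perm=config.n_permutations,
                seed=config.seed + gi,
                tail="greater",
            )
            roi = roi_summary(StatMap(sm), roi_mask=roi_in_fit)
            deltas[predictor] = delta
            group_report[predictor] = {
                "unique_power": delta,
                "smoothed": sm,
                "p_min": float(test.p.min()),
                "significant": bool((test.p <= config.alpha).any()),
                "roi_mean": roi.mean,
                "cohens_d": roi.d,
                "roi_per_subject": roi.per_subject,
            }
        if "first_phoneme_split" in power_arr:
            t_split = paired_permutation_test(
                power_arr["first_phoneme_split"],
                power_arr["full"],
                edges=subgraph_edges(geometry, source_idx),
                n_perm=config.n_permutations,
                seed=config.seed + 100 + gi,
                tail="greater",
            )
            group_report["first_phoneme_split"] = {
                "p_min": float(t_split.p.min()),
                "better": bool((t_split.p <= config.alpha).any()),
            }
        report["groups"][name] = group_report
        if "surprisal" in deltas and "entropy" in deltas:
            group_summaries[name] = {
                "entropy_roi": group_report["entropy"]["roi_per_subject"],
                "surprisal_roi": group_report["surprisal"]["roi_per_subject"],
            }

    names = list(report["groups"])
    if len(group_summaries) >= 2:
        g1, g2 = (group_summaries[n] for n in names[:2])
        t, df, p = ratio_interaction_test(
            g1["entropy_roi"], g1["surprisal_roi"],
            g2["entropy_roi"], g2["surprisal_roi"],
        )
        report["ratio_interaction"] = {
            "t": t,
            "df": df,
            "p": p,
            "significant": p <= config.alpha,
            "groups": names[:2],
        }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(format_report(report))
        (out / "report.json").write_text(_json_report(report))
        _summary_table(report).to_csv(out / "summary.tsv", sep="\t", index=False)
    return report


def _summary_table(report: dict):
    """Per-group, per-predictor summary rows (TSV-friendly)."""
    import pandas as pd

    rows = []
    for group, g in report["groups"].items():
        for predictor in ("surprisal", "entropy"):
            if predictor not in g:
                continue
            r = g[predictor]
            rows.append(
                {
                    "group": group,
                    "predictor": predictor,
                    "n_subjects": g["n_subjects"],
                    "roi_mean_unique_power": r["roi_mean"],
                    "cohens_d": r["cohens_d"],
                    "p_min": r["p_min"],
                    "significant": r["significant"],
                }
            )
    return pd.DataFrame(rows)


def geometry_subset(geometry, idx):
    from .stats import SourceGeometry

    idx = np.asarray(idx)
    return SourceGeometry(
        geometry.coordinates[idx],
        subgraph_edges(geometry, idx),
        geometry.orientations[idx] if geometry.orientations is not None else None,
        geometry.roi_mask[idx] if geometry.roi_mask is not None else None,
        geometry.hemisphere[idx] if geometry.hemisphere is not None else None,
    )


def subgraph_edges(geometry, idx):
    idx = np.asarray(idx)
    lookup = -np.ones(geometry.n_sources, np.int64)
    lookup[idx] = np.arange(len(idx))
    a = lookup[geometry.edges[:, 0]]
    b = lookup[geometry.edges[:, 1]]
    keep = (a >= 0) & (b >= 0)
    return np.column_stack([a[keep], b[keep]])


def format_report(report: dict) -> str:
    """Human-readable model-comparison report (deterministic)."""
    lines = [
        "Model comparison report",
        f"  config: {report['config_hash']}  seed: {report['seed']}",
        f"  models: {', '.join(report['models'])}",
        "",
    ]
    for name, g in report["groups"].items():
        lines.append(f"group {name!r} (n={g['n_subjects']}):")
        for predictor in ("surprisal", "entropy"):
            if predictor not in g:
                continue
            r = g[predictor]
            sig = "significant" if r["significant"] else "not significant"
            lines.append(
                f"  {predictor:10s} unique power: ROI mean {r['roi_mean']:+.5f}, "
                f"d = {r['cohens_d']:.2f}, min p = {r['p_min']:.4f} ({sig})"
            )
        if "first_phoneme_split" in g:
            r = g["first_phoneme_split"]
            verdict = "better" if r["better"] else "not better"
            lines.append(
                f"  first-phoneme split model: min p = {r['p_min']:.4f} "
                f"({verdict} than uniform)"
            )
        lines.append("")
    if "ratio_interaction" in report:
        ri = report["ratio_interaction"]
        sig = "significant" if ri["significant"] else "not significant"
        lines.append(
            f"entropy/surprisal ratio interaction ({ri['groups'][0]} vs "
            f"{ri['groups'][1]}): t({ri['df']:.0f}) = {ri['t']:.3f}, "
            f"p = {ri['p']:.4f} ({sig})"
        )
    return "\n".join(lines) + "\n"


def _json_report(report: dict) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer, np.bool_)):
            return o.item()
        return str(o)

    return json.dumps(report, default=default, indent=2, sort_keys=True)
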