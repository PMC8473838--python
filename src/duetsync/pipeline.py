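"""End-to-end orchestration: simulate -> behavior -> spectra -> envelopes.

The runner processes one simulated pair at a time (EEG arrays are never
resident for more than one pair), accumulates tidy summary tables keyed by
(pair_id, condition), computes the cohort-level statistics, and writes
everything as CSV/JSON.  Identical config + seed reproduces identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import envelope as envm
from . import spectral as spc
from . import ssd as ssdm
from .melody import MelodySpec, make_melody_spec
from .simulate import CohortConfig, EEGSimConfig, PairData, iter_cohort, mean_beat_period_ms

__all__ = ["RunConfig", "run_pipeline", "analyze_pair"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    seed: int = 0
    out_dir: str = "duetsync_out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    spectral: spc.SpectralConfig = field(default_factory=spc.SpectralConfig)
    ssd_band: tuple[float, float] = (1.5, 3.5)
    ssd_flank_width: float = 1.0
    ssd_gap: float = 0.5
    do_behavior: bool = True
    do_spectra: bool = True
    do_envelopes: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        eeg = d["cohort"]["eeg"]
        if eeg.get("topography") is not None:
            eeg["topography"] = [float(v) for v in eeg["topography"]]
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = dict(d.pop("cohort", {}))
        eeg = dict(cohort.pop("eeg", {}))
        if eeg.get("topography") is not None:
            eeg["topography"] = np.asarray(eeg["topography"], float)
        if "channel_names" in eeg:
            eeg["channel_names"] = list(eeg["channel_names"])
        if "conditions" in cohort:
            cohort["conditions"] = tuple(cohort["conditions"])
        if "solo_period_range_ms" in cohort:
            cohort["solo_period_range_ms"] = tuple(cohort["solo_period_range_ms"])
        spectral = dict(d.pop("spectral", {}))
        for key in ("noise_offsets", "roi"):
            if key in spectral:
                spectral[key] = tuple(spectral[key])
        if "ssd_band" in d:
            d["ssd_band"] = tuple(d["ssd_band"])
        return cls(
            cohort=CohortConfig(eeg=EEGSimConfig(**eeg), **cohort),
            spectral=spc.SpectralConfig(**spectral),
            **d,
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _retained_windows(rec, retained_reps: set[int]) -> pd.DataFrame:
    return rec.rep_windows[rec.rep_windows["repetition_index"].isin(retained_reps)]


def analyze_pair(pair: PairData, cfg: RunConfig, melody: MelodySpec) -> dict:
    """All per-pair measures; EEG arrays are released when this returns."""
    out: dict = {"pair_id": pair.pair_id, "behavior_rows": [], "psd_rows": [],
                 "aligned": {}, "raw_envelopes": {}, "n_excluded": 0, "n_total": 0}

    # -- error filtering + solo rates ------------------------------------
    solo_ioi = {}
    for perf, trials in pair.solo_trials.items():
        retained, excluded = bhv.apply_error_filter(trials, melody)
        out["n_excluded"] += len(excluded)
        out["n_total"] += len(trials)
        solo_ioi[perf] = float(np.mean([
            bhv.quarter_level_iois(t, melody).mean_ioi_ms for t in retained
        ]))

    for condition, roles in pair.duet_trials.items():
        leader_id = pair.leader_of[condition]
        follower_id = pair.performer_b if leader_id == pair.performer_a else pair.performer_a
        lt_ret, lt_exc = bhv.apply_error_filter(roles["Leader"], melody)
        ft_ret, ft_exc = bhv.apply_error_filter(roles["Follower"], melody)
        out["n_excluded"] += len(lt_exc) + len(ft_exc)
        out["n_total"] += len(roles["Leader"]) + len(roles["Follower"])
        lt_by_rep = {t.repetition_index: t for t in lt_ret}
        ft_by_rep = {t.repetition_index: t for t in ft_ret}
        common_reps = sorted(set(lt_by_rep) & set(ft_by_rep))
        if not common_reps:
            logger.warning("pair %d %s: no co-retained repetitions", pair.pair_id, condition)
            continue
        asyncs = [
            bhv.duet_asynchronies(lt_by_rep[r], ft_by_rep[r], melody) for r in common_reps
        ]
        agg = bhv.aggregate_asynchronies(asyncs)
        duet_ioi = agg.mean_duet_ioi_ms
        f_duet = 1000.0 / duet_ioi
        out["behavior_rows"].append({
            "pair_id": pair.pair_id, "condition": condition,
            "leader": leader_id, "follower": follower_id,
            "leader_solo_ioi_ms": solo_ioi[leader_id],
            "follower_solo_ioi_ms": solo_ioi[follower_id],
            "duet_ioi_ms": duet_ioi, "duet_rate_hz": f_duet,
            "signed_asynchrony": agg.signed_mean,
            "absolute_asynchrony": agg.absolute_mean,
            "n_repetitions": len(common_reps),
        })

        retained_reps = set(common_reps)

        # -- spectra -----------------------------------------------------
        if cfg.do_spectra and pair.duet_eeg is not None:
            for perf, rec in pair.duet_eeg[condition].items():
                filt = spc.prefilter(rec, cfg.spectral)
                filt.rep_windows = _retained_windows(filt, retained_reps)
                epochs = spc.epoch_fixed_window(filt, cfg.spectral)
                freqs, mlog = spc.mean_log_psd(epochs, cfg.spectral)
                norm = spc.lognormalize(freqs, mlog, cfg.spectral, rec.ch_names)
                aligned = spc.align_to_duet_rate(norm, f_duet, cfg.spectral)
                roi_vals = spc.roi_mean(aligned, rec.ch_names, cfg.spectral.roi)
                role = "Leader" if perf == leader_id else "Follower"
                out["aligned"].setdefault(condition, {})[perf] = {
                    "roi": roi_vals, "channel_mean": aligned.mean(axis=0), "role": role,
                }
                c = cfg.spectral.align_halfwidth_bins
                out["psd_rows"].append({
                    "pair_id": pair.pair_id, "condition": condition,
                    "performer": perf, "role": role,
                    "roi_psd_at_rate": float(roi_vals[c]),
                    "channel_mean_psd_at_rate": float(aligned.mean(axis=0)[c]),
                })

        # -- envelopes ---------------------------------------------------
        if cfg.do_envelopes and pair.duet_eeg is not None and pair.solo_eeg is not None:
            env_by_role = {}
            for perf, rec in pair.duet_eeg[condition].items():
                ssd_fit = ssdm.fit_ssd(
                    pair.solo_eeg[perf], band=cfg.ssd_band,
                    flank_width=cfg.ssd_flank_width, gap=cfg.ssd_gap,
                )
                w, _ = ssdm.select_component(ssd_fit, roi=cfg.spectral.roi)
                rec_ret = dataclasses.replace(
                    rec, rep_windows=_retained_windows(rec, retained_reps)
                )
                envs = envm.extract_envelope(rec_ret, w, f_duet, melody)
                role = "Leader" if perf == leader_id else "Follower"
                env_by_role[role] = envs
            out["raw_envelopes"][condition] = env_by_role
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all enabled stages over a simulated cohort; write outputs."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    melody = make_melody_spec()
    if not (cfg.do_behavior or cfg.do_spectra or cfg.do_envelopes):
        logger.warning("all stages disabled: nothing to do")
        return {"config_hash": cfg.config_hash(), "stages": []}

    cohort_cfg = dataclasses.replace(
        cfg.cohort, seed=cfg.seed,
        simulate_eeg=cfg.cohort.simulate_eeg and (cfg.do_spectra or cfg.do_envelopes),
    )

    behavior_rows, psd_rows = [], []
    aligned_all: dict = {}
    envelopes_all: dict = {}
    n_excluded = n_total = 0
    for pair in iter_cohort(cohort_cfg, melody=melody):
        res = analyze_pair(pair, cfg, melody)
        behavior_rows += res["behavior_rows"]
        psd_rows += res["psd_rows"]
        for condition, per_perf in res["aligned"].items():
            aligned_all.setdefault(condition, {})[res["pair_id"]] = per_perf
        for condition, env_by_role in res["raw_envelopes"].items():
            envelopes_all.setdefault(condition, {})[res["pair_id"]] = env_by_role
        n_excluded += res["n_excluded"]
        n_total += res["n_total"]
        logger.info("pair %d analyzed", res["pair_id"])

    summary = pd.DataFrame(behavior_rows)
    stats: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_pairs": cohort_cfg.n_pairs,
        "repetitions_excluded": n_excluded,
        "repetitions_total": n_total,
        "exclusion_pct": 100.0 * n_excluded / max(n_total, 1),
    }

    if cfg.do_behavior and len(summary):
        summary.to_csv(out_dir / "behavior_summary.csv", index=False)
        if summary.groupby("condition").size().min() >= 4:
            stats["detuning_vs_asynchrony"] = bhv.detuning_vs_asynchrony(summary)
            stats["duet_rate_regression"] = {}
            for condition, grp in summary.groupby("condition"):
                reg = bhv.duet_rate_regression(
                    1000.0 / grp["leader_solo_ioi_ms"],
                    1000.0 / grp["follower_solo_ioi_ms"],
                    grp["duet_rate_hz"],
                )
                stats["duet_rate_regression"][condition] = dataclasses.asdict(reg)

    if cfg.do_spectra and psd_rows:
        psd_frame = pd.DataFrame(psd_rows)
        psd_frame.to_csv(out_dir / "psd_summary.csv", index=False)
        spectra_rows = []
        stats["peak_test"] = {}
        for condition, by_pair in aligned_all.items():
            roi_stack = []
            for pair_id, per_perf in sorted(by_pair.items()):
                for perf, vals in sorted(per_perf.items()):
                    roi_stack.append(vals["roi"])
                    for off, v in zip(
                        range(-cfg.spectral.align_halfwidth_bins,
                              cfg.spectral.align_halfwidth_bins + 1), vals["roi"]
                    ):
                        spectra_rows.append({
                            "pair_id": pair_id, "performer": perf, "role": vals["role"],
                            "condition": condition, "bin_offset": off, "roi_value": float(v),
                        })
            if len(roi_stack) >= 6:
                stats["peak_test"][condition] = spc.peak_test(
                    np.stack(roi_stack), cfg.spectral
                )
        pd.DataFrame(spectra_rows).to_csv(out_dir / "aligned_spectra.csv", index=False)
        if cfg.do_behavior and len(summary) and len(psd_frame):
            merged = psd_frame.merge(
                summary[["pair_id", "condition", "absolute_asynchrony"]],
                on=["pair_id", "condition"],
            )
            stats["psd_vs_synchrony"] = {}
            for (condition, role), grp in merged.groupby(["condition", "role"]):
                if len(grp) >= 4 and grp["roi_psd_at_rate"].nunique() > 1:
                    stats["psd_vs_synchrony"][f"{condition}/{role}"] = (
                        spc.psd_synchrony_correlation(
                            grp["roi_psd_at_rate"], grp["absolute_asynchrony"]
                        )
                    )
            # two-predictor model: asynchrony from leader and follower PSD
            stats["asynchrony_psd_regression"] = {}
            wide = merged.pivot_table(
                index=["pair_id", "condition"], columns="role",
                values="roi_psd_at_rate",
            ).join(
                merged.groupby(["pair_id", "condition"])["absolute_asynchrony"].first()
            ).reset_index()
            for condition, grp in wide.groupby("condition"):
                if len(grp) >= 4:
                    try:
                        reg = spc.asynchrony_psd_regression(
                            grp["Leader"].to_numpy(), grp["Follower"].to_numpy(),
                            grp["absolute_asynchrony"].to_numpy(),
                        )
                    except ValueError:
                        continue
                    stats["asynchrony_psd_regression"][condition] = dataclasses.asdict(reg)

    if cfg.do_envelopes and envelopes_all:
        aec_rows = []
        observed_z: dict = {}
        surrogate_z: dict = {}
        for condition, by_pair in envelopes_all.items():
            for pair_id, env_by_role in by_pair.items():
                m = envm.min_grid_density(
                    env_by_role["Leader"] + env_by_role["Follower"]
                )
                ls = [envm.event_resample(e, melody, m) for e in env_by_role["Leader"]]
                fs_ = [envm.event_resample(e, melody, m) for e in env_by_role["Follower"]]
                res = envm.condition_aec(ls, fs_)
                observed_z.setdefault(pair_id, []).append(res["fisher_z_mean"])
                aec_rows.append({
                    "pair_id": pair_id, "condition": condition,
                    "observed_r": res["r_mean"], "n_repetitions": res["n_repetitions"],
                })
            if len(by_pair) >= 3:
                sur = envm.surrogate_aecs(by_pair, melody)
                for pair_id, r_sur in sur.items():
                    surrogate_z.setdefault(pair_id, []).append(float(np.arctanh(r_sur)))
        aec_frame = pd.DataFrame(aec_rows)
        pair_ids = sorted(observed_z)
        observed = np.array([np.tanh(np.mean(observed_z[p])) for p in pair_ids])
        stats["aec"] = {
            "pair_ids": pair_ids,
            "observed_mean_r": float(envm.fisher_z_mean(observed)),
            "observed_per_pair": [float(v) for v in observed],
        }
        if surrogate_z:
            surrogate = np.array([np.tanh(np.mean(surrogate_z[p])) for p in pair_ids])
            stats["aec"]["surrogate_per_pair"] = [float(v) for v in surrogate]
            stats["aec"]["surrogate_mean_r"] = float(envm.fisher_z_mean(surrogate))
            stats["aec"]["binomial"] = envm.binomial_comparison(observed, surrogate)
            aec_frame = aec_frame.merge(
                pd.DataFrame({"pair_id": pair_ids, "surrogate_mean_r": surrogate}),
                on="pair_id",
            )
        aec_frame.to_csv(out_dir / "aec_summary.csv", index=False)

    (out_dir / "stats.json").write_text(json.dumps(stats, indent=2, default=float))
    cfg.to_yaml(out_dir / "run_config.yaml")
    return stats
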