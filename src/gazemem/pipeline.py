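"""End-to-end orchestration: simulate -> preprocess -> analyse -> report.

Each stage reads and writes plain CSV/JSON (gaze samples optionally HDF5),
so any stage can be re-run in isolation.  A run manifest records the
package version, configuration, seeds and per-stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behaviour, inference, preprocess, rsa, saccades, simulate
from .dataset import EVENTS, GazeDataset

__all__ = ["RunConfig", "load_config", "run_simulate", "run_analyse", "run_report"]

DELAY1_LAST_SECOND = (EVENTS["test1_on"] - 1000.0, EVENTS["test1_on"])
DELAY2_LAST_SECOND = (EVENTS["test2_on"] - 1000.0, EVENTS["test2_on"])


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration (see ``load_config`` for the YAML layout)."""

    synthetic: simulate.SyntheticConfig = dataclasses.field(
        default_factory=simulate.SyntheticConfig)
    n_participants: int = 20
    reject_threshold_px: float = 100.0
    n_bins: int = 8
    bin_window_ms: tuple = (250.0, 1000.0)
    n_perm: int = 2000
    alpha_sample: float = 0.05
    bf_smoothing_ms: float = 50.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    syn = simulate.SyntheticConfig(**raw.pop("synthetic", {}))
    return RunConfig(synthetic=syn, **raw)


def _manifest(out_dir: Path, config: RunConfig, stage: str, files: list[str]) -> None:
    man_path = out_dir / "manifest.json"
    man = json.loads(man_path.read_text()) if man_path.exists() else {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()).hexdigest(),
        "stages": {},
    }
    man["stages"][stage] = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": {f: hashlib.sha256((out_dir / f).read_bytes()).hexdigest()[:16]
                  for f in files if (out_dir / f).exists()},
    }
    man_path.write_text(json.dumps(man, indent=2, default=str))


def run_simulate(config: RunConfig, out_dir) -> list[Path]:
    """Generate the synthetic group and write one HDF5 + trial CSV per
    participant."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.synthetic.n_trials <= 0:
        raise ValueError("n_trials must be positive")
    cfg = dataclasses.replace(config.synthetic, seed=config.seed)
    datasets = simulate.generate_group(cfg, config.n_participants)
    files = []
    for ds in datasets:
        h5 = out_dir / f"{ds.participant_id}.h5"
        ds.to_hdf5(h5)
        csv = out_dir / f"{ds.participant_id}_trials.csv"
        ds.trials.to_csv(csv, index=False)
        files += [h5.name, csv.name]
    _manifest(out_dir, config, "simulate", files)
    return [out_dir / f for f in files]


def _participant_analysis(ds: GazeDataset, config: RunConfig) -> dict:
    """All per-participant stages on one dataset."""
    ds = preprocess.zero_center(ds)
    ds, rej = preprocess.reject_artifacts(ds, config.reject_threshold_px)
    ds = preprocess.extract_epochs(ds)
    qc = preprocess.participant_qc(ds.trials, rej, ds.participant_id)
    ep1, ep2 = ds.epochs[1], ds.epochs[2]
    trials, t2 = ds.trials, ds.trials[ds.trials["has_test2"].astype(bool)]

    out = {"qc": qc, "time_ms": {1: ep1.time_ms, 2: ep2.time_ms}}
    enc = {}
    for stim in (1, 2):
        enc[stim] = rsa.single_trial_encoding(ep1, trials[f"ori_idx_{stim}"].to_numpy())
    out["encoding_epoch1"] = enc
    cued = trials["cued_first"].to_numpy()
    out["cond_means"] = {
        (stim, "cued" if c == stim else "uncued"):
            rsa.condition_timecourse(enc[stim], cued == c)
        for stim in (1, 2) for c in (1, 2)
    }
    # epoch 2: encoding of the second-cued orientation
    second = 3 - t2["cued_first"].to_numpy()
    idx2 = np.array([t2[f"ori_idx_{s}"].iloc[i] for i, s in enumerate(second)])
    out["encoding_epoch2_secondcued"] = rsa.single_trial_encoding(ep2, idx2)

    # within/between objects for each stimulus (epoch 1)
    wb = {}
    for stim in (1, 2):
        w, b = rsa.within_between_encoding(
            ep1, trials[f"ori_idx_{stim}"].to_numpy(),
            trials[f"object_{stim}"].to_numpy() - 1)
        wb[stim] = (w, b)
    out["within_between"] = wb

    # concurrency binning: sort by S2 encoding after S2 onset, report S1
    prof = rsa.bin_by_encoding_strength(
        enc[2], enc[1], ep1.time_ms,
        window=(EVENTS["stim2_on"] + config.bin_window_ms[0],
                EVENTS["stim2_on"] + config.bin_window_ms[1]),
        n_bins=config.n_bins)
    out["bin_profile"] = prof

    # bias contrast on the cued item, last second of delay 1
    cued_idx = np.array([trials[f"ori_idx_{c}"].iloc[i] for i, c in enumerate(cued)])
    out["bias_epoch1"] = rsa.bias_model_contrast(ep1, cued_idx, last_ms=DELAY1_LAST_SECOND)
    out["bias_epoch2"] = rsa.bias_model_contrast(ep2, idx2, last_ms=DELAY2_LAST_SECOND)

    # behaviour: pooled psychometric fit + accuracy per cell
    tested_ori, tested_off, tested_resp = [], [], []
    for test in (1, 2):
        sub = trials if test == 1 else t2
        stim_col = sub["cued_first"] if test == 1 else 3 - sub["cued_first"]
        ori = np.array([sub[f"orientation_{s}"].iloc[i] for i, s in enumerate(stim_col)])
        tested_ori.append(ori)
        tested_off.append(sub[f"probe_offset_{test}"].to_numpy())
        tested_resp.append((sub[f"response_{test}"] == "clockwise").to_numpy())
    out["psych_fit"] = behaviour.fit_grid(np.concatenate(tested_ori),
                                          np.concatenate(tested_off),
                                          np.concatenate(tested_resp))
    out["accuracy"] = behaviour.accuracy_summary(trials)

    # microsaccades
    sacc = saccades.detect_dataset(ds)
    out["saccades"] = sacc
    out["saccade_directions"] = saccades.direction_analysis(sacc, trials)
    return out


def run_analyse(config: RunConfig, data_dir, out_dir,
                datasets: list[GazeDataset] | None = None) -> dict:
    """Analyse a directory of participant HDF5 files (or in-memory datasets)
    and write group-level CSV/JSON results."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if datasets is None:
        paths = sorted(Path(data_dir).glob("*.h5"))
        if not paths:
            raise FileNotFoundError(f"no participant files in {data_dir}")
        datasets = [GazeDataset.from_hdf5(p) for p in paths]

    per = [_participant_analysis(ds, config) for ds in datasets]
    kept = [p for p in per if not p["qc"].excluded]
    group: dict = {"n_participants": len(per), "n_excluded": len(per) - len(kept)}

    # group encoding time courses (cued/uncued per stimulus)
    time1 = kept[0]["time_ms"][1]
    cond_tc = {}
    for key in kept[0]["cond_means"]:
        mat = np.vstack([p["cond_means"][key] for p in kept])
        cond_tc[key] = mat
    group["cond_timecourses"] = cond_tc

    # cluster tests: cued encoding epoch 1 for each stimulus
    cluster = {}
    for stim in (1, 2):
        mat = cond_tc[(stim, "cued")]
        res = inference.cluster_permutation(mat, time1, config.alpha_sample,
                                            config.n_perm, seed=config.seed)
        cluster[f"stim{stim}_cued"] = res
    group["clusters"] = cluster

    # object specificity: within - between, delay-1 average and BF time course
    wb_diff = {}
    for stim in (1, 2):
        diff = np.vstack([
            np.nanmean(p["within_between"][stim][0], axis=0)
            - np.nanmean(p["within_between"][stim][1], axis=0)
            for p in kept])
        wb_diff[stim] = diff
    group["wb_diff"] = wb_diff
    group["wb_bf"] = {
        stim: inference.bf01_timecourse(wb_diff[stim], time1,
                                        smoothing_ms=config.bf_smoothing_ms)
        for stim in (1, 2)}

    # bias contrast summary (last second of each delay)
    for epoch_key, label in (("bias_epoch1", "delay1"), ("bias_epoch2", "delay2")):
        vals = np.array([np.nanmean(p[epoch_key]["contrast_mean"]) for p in kept])
        group[f"bias_contrast_{label}"] = inference.one_sample_test(vals, tail="greater")

    # behaviour: accuracy cells, ANOVA, mnemonic slopes, psychometric params
    acc = np.array([[row for row in p["accuracy"]["accuracy_pct"]] for p in kept])
    group["accuracy_levels"] = acc  # columns ordered by mnemonic level
    cells = np.empty((len(kept), 2, 2))
    for i, p in enumerate(kept):
        a = p["accuracy"].set_index(["test", "stimulus"])["accuracy_pct"]
        cells[i] = [[a[(1, 1)], a[(1, 2)]], [a[(2, 1)], a[(2, 2)]]]
    group["accuracy_anova"] = inference.rm_anova_2x2(cells)
    slopes = rsa.mnemonic_distance_summary(acc)
    group["accuracy_slope"] = inference.one_sample_test(slopes)
    group["psych_params"] = pd.DataFrame(
        [{"participant": d.participant_id, "B": p["psych_fit"].params.B,
          "s": p["psych_fit"].params.s, "c": p["psych_fit"].params.c,
          "sse": p["psych_fit"].sse}
         for d, p in zip(datasets, per) if not p["qc"].excluded])

    # binning profile slopes
    bin_slopes = np.array([rsa.bin_profile_slope(p["bin_profile"]) for p in kept])
    group["bin_slope"] = inference.one_sample_test(bin_slopes)
    top_bin = np.array([p["bin_profile"]["mean_report_encoding"].iloc[-1] for p in kept])
    group["top_bin_test"] = inference.one_sample_test(top_bin)

    # saccade direction analysis pooled over participants
    group["saccade_directions"] = pd.concat(
        [p["saccade_directions"].assign(participant=d.participant_id)
         for d, p in zip(datasets, per)], ignore_index=True)

    _write_outputs(group, kept, time1, out_dir)
    _plot_timecourses(group, time1, out_dir / "encoding_timecourses.png")
    _manifest(out_dir, config, "analyse", [p.name for p in out_dir.glob("*.csv")])
    return group


def _write_outputs(group: dict, kept: list, time1: np.ndarray, out_dir: Path) -> None:
    rows = []
    for (stim, cue), mat in group["cond_timecourses"].items():
        mean = np.nanmean(mat, axis=0)
        sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(mat.shape[0])
        rows.append(pd.DataFrame({"stimulus": stim, "condition": cue,
                                  "time_ms": time1, "mean_r": mean, "sem": sem}))
    pd.concat(rows, ignore_index=True).to_csv(out_dir / "encoding_timecourses.csv",
                                              index=False)
    group["psych_params"].to_csv(out_dir / "psychometric_fits.csv", index=False)
    group["saccade_directions"].to_csv(out_dir / "saccade_directions.csv", index=False)

    summary = {
        "n_participants": group["n_participants"],
        "n_excluded": group["n_excluded"],
        "clusters": {k: [dataclasses.asdict(c) for c in v.clusters]
                     for k, v in group["clusters"].items()},
        "bias_contrast_delay1": dataclasses.asdict(group["bias_contrast_delay1"]),
        "bias_contrast_delay2": dataclasses.asdict(group["bias_contrast_delay2"]),
        "accuracy_anova": group["accuracy_anova"],
        "accuracy_slope": dataclasses.asdict(group["accuracy_slope"]),
        "bin_slope": dataclasses.asdict(group["bin_slope"]),
        "top_bin_test": dataclasses.asdict(group["top_bin_test"]),
        "mean_psych_params": group["psych_params"][["B", "s", "c"]].mean().to_dict(),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))


def _plot_timecourses(group: dict, time1: np.ndarray, path: Path) -> None:
    """Group-mean encoding time courses (cued/uncued per stimulus)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for (stim, cue), mat in sorted(group["cond_timecourses"].items()):
        mean = np.nanmean(mat, axis=0)
        sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(mat.shape[0])
        line, = ax.plot(time1, mean, label=f"stimulus {stim} ({cue})",
                        lw=1.0, alpha=0.9)
        ax.fill_between(time1, mean - sem, mean + sem,
                        color=line.get_color(), alpha=0.2, lw=0)
    for ev in ("stim1_on", "stim2_on", "cue1_on", "test1_on"):
        ax.axvline(EVENTS[ev], color="grey", ls=":", lw=0.8)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("time from Stimulus 1 onset (ms)")
    ax.set_ylabel("orientation encoding (Pearson r)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_report(results_dir, out_path=None) -> str:
    """One-page plain-text report from a results directory."""
    results_dir = Path(results_dir)
    summary = json.loads((results_dir / "summary.json").read_text())
    lines = ["gazemem analysis report", "=" * 40,
             f"participants analysed: {summary['n_participants']}"
             f" (excluded: {summary['n_excluded']})", ""]
    for name, clus in summary["clusters"].items():
        sig = [c for c in clus if c["p_cluster"] < 0.05]
        lines.append(f"{name}: {len(clus)} cluster(s), {len(sig)} significant")
        for c in sig[:5]:
            lines.append(f"  {c['start_ms']:.0f}-{c['end_ms']:.0f} ms, "
                         f"sum t = {c['sum_t']:.1f}, p = {c['p_cluster']:.4f}")
    for label in ("delay1", "delay2"):
        bc = summary[f"bias_contrast_{label}"]
        lines.append(f"bias contrast {label}: t({bc['df']}) = {bc['t']:.2f}, "
                     f"p = {bc['p']:.4f}, d = {bc['cohens_d']:.2f}")
    sl = summary["accuracy_slope"]
    lines.append(f"accuracy slope over mnemonic distance: t({sl['df']}) = {sl['t']:.2f},"
                 f" p = {sl['p']:.4g}")
    mp = summary["mean_psych_params"]
    lines.append(f"mean psychometric parameters: B = {mp['B']:.3f}, "
                 f"s = {mp['s']:.3f}, c = {mp['c']:.3f}")
    text = "\n".join(lines) + "\n"
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
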