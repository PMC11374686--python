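"""End-to-end orchestration and summary tables.

``run_all`` executes the full analysis chain on one session — segmentation,
trajectory clustering, spatial-information tests in all reference frames,
identity/conspecific permutation tests, the conjunctive-coding model and
remapping statistics — and returns tidy DataFrames (optionally written as
TSVs with a JSON run manifest).  ``summarize`` reduces the per-unit results
to the population fractions with their analyzable-unit denominators.
"""
from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conjunctive import (count_multilocation_modulation, fit_landing_model)
from .frames import build_frames
from .identity import (conspecific_presence_tests, derive_seed, event_trials,
                       identity_permutation_tests,
                       identity_tests_excluding_conspecific, reward_metrics)
from .ratemaps import linearize_flights, BinnedTrajectory1D
from .remapping import map_metrics_1d, null_trial_shuffle, remapping_score
from .session import Session, format_fraction
from .spatial_info import si_by_frame, preferred_vs_nonpreferred

logger = logging.getLogger("batmap")

FRAMES = ("self_2d", "self_1d", "conspecific_1d", "human_2d_pooled",
          "human_2d_identity")


def _si_rows(results):
    rows = []
    for r in results:
        rows.append({
            "unit": r.unit_id, "frame": r.frame, "key": r.key,
            "analyzable": r.analyzable, "empirical_si": r.empirical_si,
            "null_mean": r.null_mean, "p": r.p_value,
            "bonferroni_n": r.bonferroni_n, "significant": r.significant,
            "normalized_si": r.normalized_si, "note": r.note,
        })
    return rows


def _perm_rows(results):
    rows = []
    for r in results:
        rows.append({
            "unit": r.unit_id, "event": r.event, "location": r.location_id,
            "variant": r.variant, "analyzable": r.analyzable,
            "n1": r.n1, "n2": r.n2, "diff_hz": r.empirical_diff,
            "sign": r.sign, "p": r.p, "n_perm": r.n_perm,
            "bonferroni_n": r.bonferroni_n, "significant": r.significant,
            "note": r.note,
        })
    return rows


def _remapping_for_unit(frames, unit, si_df, seed):
    """1D remapping metrics per significant trajectory of one unit."""
    ses = frames.session
    cfg = frames.config
    bat = ses.recorded_bat
    rows, maps_by_human = [], {}
    sig = si_df[(si_df["unit"] == unit.unit_id) & (si_df["frame"] == "self_1d")
                & (si_df["significant"] == True)]  # noqa: E712
    for cid in sig["key"]:
        cluster = frames.clusters[bat][int(cid)]
        by_human = {}
        for m in cluster.member_ids:
            h = frames.flights[bat][m].human_at_landing
            if h is not None:
                by_human.setdefault(h, []).append(m)
        if len(by_human) != 2:
            continue
        lin_by_human, maps = {}, {}
        samples_all = []
        ok = True
        for h, members in sorted(by_human.items()):
            samples = [frames.flight_samples[bat][m] for m in members]
            samples_all.extend(samples)
            lin, length = linearize_flights(samples)
            counts = [unit.spike_train.count_in(f.t[0], f.t[-1]) for f in lin]
            if (sum(1 for c in counts if c > 0) < cfg.min_flights_with_spikes_1d
                    or sum(counts) < cfg.min_spikes_1d):
                ok = False
                break
            lin_by_human[h] = lin
        if not ok:
            continue
        lin_all, length = linearize_flights(samples_all)
        binned_all = BinnedTrajectory1D(lin_all, length, cfg.bin_size,
                                        cfg.kernel_1d_taps, cfg.kernel_1d_sigma_bins)
        for h in lin_by_human:
            b = BinnedTrajectory1D(lin_by_human[h], length, cfg.bin_size,
                                   cfg.kernel_1d_taps, cfg.kernel_1d_sigma_bins)
            maps[h] = b.rate_map(unit.spike_train.spike_times)
        h1, h2 = sorted(maps)
        r, dist = map_metrics_1d(maps[h1], maps[h2])
        try:
            score = remapping_score(maps[h1].mean_rate, maps[h2].mean_rate)
        except Exception:
            continue
        null_sc = null_trial_shuffle(
            binned_all, lin_by_human, unit.spike_train.spike_times,
            cfg.n_shuffles, derive_seed(seed, unit.unit_id, "remap", cid))
        rows.append({
            "unit": unit.unit_id, "trajectory": cid, "correlation": r,
            "peak_distance_m": dist, "score": score,
            "score_null_p95": float(np.nanquantile(null_sc, 0.95)),
            "score_p": float((1 + np.nansum(null_sc >= score))
                             / (1 + np.sum(np.isfinite(null_sc)))),
        })
        maps_by_human.setdefault(cid, {})[unit.unit_id] = (maps[h1], maps[h2])
    return rows, maps_by_human


def run_all(session: Session, seed: int = 0, out_dir=None,
            hand_events: dict | None = None,
            frames_list=FRAMES) -> dict:
    """Run the full pipeline on one session; returns a dict of DataFrames."""
    cfg = session.config
    frames = build_frames(session, hand_events, seed)
    si_rows, perm_rows, conj_rows, reward_rows = [], [], [], []
    perm_by_unit = {}
    for unit in session.units:
        for frame in frames_list:
            if frame == "conspecific_1d" and session.conspecific is None:
                continue
            try:
                si_rows.extend(_si_rows(si_by_frame(frames, unit, frame, seed)))
            except Exception as exc:
                raise RuntimeError(f"stage si/{frame} failed for unit "
                                   f"{unit.unit_id}: {exc}") from exc
        trials = event_trials(frames.flights[session.recorded_bat],
                              unit.spike_train,
                              {"take_off": cfg.takeoff_window,
                               "landing": cfg.landing_window})
        full = identity_permutation_tests(trials, unit.unit_id, cfg, seed)
        perm_by_unit[unit.unit_id] = full
        perm_rows.extend(_perm_rows(full))
        perm_rows.extend(_perm_rows(
            conspecific_presence_tests(trials, unit.unit_id, cfg, seed)))
        perm_rows.extend(_perm_rows(
            identity_tests_excluding_conspecific(trials, unit.unit_id, cfg, seed)))
        landing = trials[(trials["event"] == "landing") & trials["human"].notna()]
        if landing["human"].nunique() >= 2 and landing["location"].nunique() >= 2:
            m = fit_landing_model(landing["rate"], landing["human"],
                                  landing["location"], unit.unit_id, cfg.alpha,
                                  cfg.conjunctive_strict_interaction)
            conj_rows.append({
                "unit": m.unit_id, "analyzable": m.analyzable,
                "p_human": m.p_human, "p_location": m.p_location,
                "p_interaction": m.p_interaction,
                "coding_class": m.coding_class, "note": m.note,
            })
        rm = reward_metrics(unit.spike_train, trials, cfg)
        reward_rows.append({"unit": unit.unit_id,
                            "baseline_hz": rm["baseline_hz"],
                            "spearman_r": rm["spearman_r"],
                            "analyzable": rm["analyzable"]})
    si_df = pd.DataFrame(si_rows)
    remap_rows = []
    for unit in session.units:
        if si_df.empty:
            break
        rows, _ = _remapping_for_unit(frames, unit, si_df, seed)
        remap_rows.extend(rows)
    multiloc = count_multilocation_modulation(perm_by_unit,
                                              cfg.min_locations_conjunctive)
    results = {
        "si": si_df,
        "identity": pd.DataFrame(perm_rows),
        "conjunctive": pd.DataFrame(conj_rows),
        "reward": pd.DataFrame(reward_rows),
        "remapping": pd.DataFrame(remap_rows),
        "multilocation": pd.DataFrame(
            [{"unit": u, "n_significant_locations": k}
             for u, k in sorted(multiloc.items())]),
    }
    results["summary"] = summarize(results)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        manifest = {"seed": int(seed), "version": __version__,
                    "python": platform.python_version(),
                    "config": cfg.to_dict(),
                    "n_units": len(session.units)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    return results


def _unit_level(df, frame):
    """(n_significant, n_analyzable) at the unit level for one SI frame."""
    sub = df[df["frame"] == frame]
    if sub.empty:
        return 0, 0
    by_unit = sub.groupby("unit").agg(
        analyzable=("analyzable", "any"), significant=("significant", "any"))
    return int(by_unit["significant"].sum()), int(by_unit["analyzable"].sum())


def _perm_unit_level(df, variant):
    sub = df[(df["variant"] == variant)]
    if sub.empty:
        return 0, 0
    by_unit = sub.groupby("unit").agg(
        analyzable=("analyzable", "any"), significant=("significant", "any"))
    return int(by_unit["significant"].sum()), int(by_unit["analyzable"].sum())


def summarize(results: dict) -> pd.DataFrame:
    """Population fractions with analyzable-unit denominators."""
    si, ident = results["si"], results["identity"]
    rows = []

    def add(name, k, n):
        rows.append({"category": name, "n_significant": k, "n_analyzable": n,
                     "fraction": format_fraction(k, n)})

    for frame, label in (("self_2d", "2D spatial information (flight)"),
                         ("self_1d", "1D spatial information (trajectories)"),
                         ("conspecific_1d", "conspecific-position information"),
                         ("human_2d_pooled", "human-position information (pooled)"),
                         ("human_2d_identity", "human-position information (per identity)")):
        if not si.empty:
            add(label, *_unit_level(si, frame))
    if not ident.empty:
        add("identity-modulated at landing/take-off",
            *_perm_unit_level(ident, "full"))
        add("conspecific-presence-modulated", *_perm_unit_level(ident, "presence"))
        add("identity-modulated (conspecific excluded)",
            *_perm_unit_level(ident, "conspecific_excluded"))
    # one-human vs both-humans selectivity
    if not si.empty:
        idf = si[(si["frame"] == "human_2d_identity") & si["analyzable"]]
        if not idf.empty:
            per_unit = idf.groupby("unit")["significant"].sum()
            any_sig = per_unit[per_unit > 0]
            add("informative for exactly one human",
                int((any_sig == 1).sum()), int(any_sig.size))
    # overlap: identity-modulated (flight) x human-position (rest)
    if not si.empty and not ident.empty:
        hm = si[(si["frame"] == "human_2d_pooled") & si["analyzable"]]
        hm_sig = set(hm[hm["significant"]]["unit"])
        hm_all = set(hm["unit"])
        im = ident[(ident["variant"] == "full") & ident["analyzable"]]
        im_sig = set(im[im["significant"]]["unit"])
        im_all = set(im["unit"])
        both_all = hm_all & im_all
        add("identity-modulated and human-position-informative",
            len(hm_sig & im_sig & both_all), len(both_all))
    return pd.DataFrame(rows)


def preferred_human_comparison(results: dict) -> dict:
    """Normalized-SI comparison for one-human-selective units."""
    si = results["si"]
    idf = si[(si["frame"] == "human_2d_identity") & si["analyzable"]]
    pairs = []
    for unit, g in idf.groupby("unit"):
        if g["significant"].sum() == 1 and len(g) == 2:
            pref = g[g["significant"]]["normalized_si"].iloc[0]
            nonp = g[~g["significant"]]["normalized_si"].iloc[0]
            pairs.append((pref, nonp))
    return preferred_vs_nonpreferred(pairs)
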