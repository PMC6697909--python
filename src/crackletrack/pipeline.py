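"""Pipeline orchestration: synthesize -> extract -> analyze -> report.

Each stage is a plain function over :class:`~crackletrack.config.PipelineConfig`
and filesystem paths; the CLI in :mod:`crackletrack.cli` is a thin wrapper.
Every stage is deterministic given (config, seed) — manifests carry SHA-256
checksums so two runs can be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import audio_io, crackle_features, preprocessing, spectral_features
from . import stats_inference as si
from .config import PipelineConfig
from .synthetic_data import CohortSpec, CrackleSpec, synth_breath, synth_cohort

log = logging.getLogger("crackletrack")

FEATURE_COLUMNS = ("count_per_insp", "onset_tercile", "f50_hz", "f95_hz",
                   "f99_hz", "tcd_ms", "idw_ms", "ldw_ms", "a2_a1", "a3_a1")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, files: list[Path]) -> Path:
    manifest = {f.name: _sha256(f) for f in sorted(files)}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# synthesize

def _place_crackles(rng: np.random.Generator, phases, audio,
                    per_insp: int) -> list[CrackleSpec]:
    """Uniform onsets within each inspiration, minimum separation kept."""
    specs: list[CrackleSpec] = []
    sep = audio.min_separation_ms * 1e-3
    for p in audio_io.inspirations(phases):
        k = int(per_insp)
        # central 15-90% of the phase: the breath envelope is audible there
        lo = p.start_s + 0.15 * p.duration_s
        hi = p.start_s + 0.90 * p.duration_s
        onsets = np.sort(rng.uniform(lo, hi, size=k))
        for _ in range(200):  # enforce separation by re-drawing clashes
            bad = np.nonzero(np.diff(onsets) < sep)[0]
            if bad.size == 0:
                break
            onsets[bad + 1] = rng.uniform(lo, hi, size=bad.size)
            onsets = np.sort(onsets)
        for t in onsets:
            f0 = rng.uniform(*audio.f0_range_hz)
            tau = rng.uniform(*audio.tau_range_ms) * 1e-3
            specs.append(CrackleSpec(float(t), float(f0), float(tau), 1.0,
                                     int(rng.choice([-1, 1]))))
    return specs


def cmd_synthesize(config: PipelineConfig, out_dir) -> Path:
    """Write the synthetic fixture set: cohort CSV, audio + annotations,
    and a checksum manifest.  Returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    cohort_spec = config.cohort
    cohort_spec.seed = config.seed
    cohort = synth_cohort(cohort_spec)
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False, float_format="%.6f")
    files.append(cohort_path)

    audio = config.audio
    phases = audio_io.protocol_phases(audio.n_breaths, audio.t_insp_s,
                                      audio.t_exp_s)
    counts = list(audio.crackles_per_insp)
    for pi in range(audio.n_patients):
        lam = counts[pi % len(counts)]
        for site_idx, site in enumerate(audio.sites):
            rid = f"A{pi:03d}__{site}"
            rng = np.random.default_rng(
                [config.seed % (2 ** 31), pi, site_idx])
            crackles = _place_crackles(rng, phases, audio, lam)
            rec, events = synth_breath(
                audio.fs, phases, crackles, snr_db=audio.snr_db,
                seed=int(rng.integers(2 ** 31)), site_label=site,
                recording_id=rid)
            wav = out / f"{rid}.wav"
            audio_io.write_wav(wav, rec)
            ph_csv = out / f"{rid}_phases.csv"
            ev_csv = out / f"{rid}_truth_events.csv"
            audio_io.write_annotations(phases, events, ph_csv, ev_csv,
                                       recording_id=rid)
            files += [wav, ph_csv, ev_csv]
    return _write_manifest(out, files)


# ---------------------------------------------------------------------------
# extract

def extract_recording(rec: audio_io.AudioRecording, phases,
                      config: PipelineConfig) -> tuple[pd.DataFrame, int]:
    """Detect and measure crackles in every inspiration of one recording.

    Returns the event table and the number of unmeasurable (excluded)
    candidates.
    """
    filtered = preprocessing.bandpass(rec, config.filter)
    rows = []
    n_excluded = 0
    for phase in audio_io.inspirations(phases):
        seg = preprocessing.extract_phase(filtered, phase)
        onsets = crackle_features.detect_crackles(seg, rec.fs,
                                                  config.detection)
        for t in onsets:
            ev = crackle_features.measure_waveform(seg, rec.fs, t,
                                                   config.detection)
            if ev is None:
                n_excluded += 1
                continue
            rel = t / phase.duration_s
            if rel >= 1.0:
                rel = np.nextafter(1.0, 0.0)
            rows.append({
                "recording_id": rec.recording_id,
                "breath_index": phase.index,
                "inspiration": f"{rec.recording_id}/{phase.index}",
                "onset_s": phase.start_s + t,
                "relative_onset": rel,
                "tercile": crackle_features.classify_tercile(rel),
                "tcd_ms": ev.tcd_ms, "idw_ms": ev.idw_ms,
                "ldw_ms": ev.ldw_ms, "a1": ev.a1, "a2": ev.a2, "a3": ev.a3,
                "a2_a1": ev.a2_a1, "a3_a1": ev.a3_a1,
                "is_fine": ev.is_fine,
            })
    cols = ["recording_id", "breath_index", "inspiration", "onset_s",
            "relative_onset", "tercile", "tcd_ms", "idw_ms", "ldw_ms",
            "a1", "a2", "a3", "a2_a1", "a3_a1", "is_fine"]
    return pd.DataFrame(rows, columns=cols), n_excluded


def cmd_extract(config: PipelineConfig, audio_dir, out_dir) -> pd.DataFrame:
    """Per-patient acoustic features from WAV + phase annotations.

    Recordings are discovered as ``<patient>__<site>.wav`` with a matching
    ``*_phases.csv``.  A recording that fails is logged and skipped; the
    run continues (callers can inspect ``extract_log.json``).
    """
    audio_dir, out = Path(audio_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wavs = sorted(audio_dir.glob("*.wav"))
    if not wavs:
        raise FileNotFoundError(f"no WAV files under {audio_dir}")

    per_patient: dict[str, dict] = {}
    extraction_log: dict[str, dict] = {}
    for wav in wavs:
        rid = wav.stem
        patient = rid.split("__")[0]
        ph_csv = audio_dir / f"{rid}_phases.csv"
        entry = per_patient.setdefault(
            patient, {"events": [], "recordings": [], "phases": [],
                      "n_insp": 0})
        try:
            rec = audio_io.read_wav(wav, multichannel=config.multichannel)
            phases = audio_io.read_phase_annotations(ph_csv)
            events, n_excl = extract_recording(rec, phases, config)
        except Exception as exc:
            log.error("extraction failed for %s: %s", rid, exc)
            extraction_log[rid] = {"status": "failed", "error": str(exc)}
            continue
        events.to_csv(out / f"{rid}_events.csv", index=False,
                      float_format="%.9f")
        extraction_log[rid] = {"status": "ok", "n_events": int(len(events)),
                               "n_excluded": int(n_excl)}
        entry["events"].append(events)
        entry["recordings"].append(preprocessing.bandpass(rec, config.filter))
        entry["phases"].append(phases)
        entry["n_insp"] += len(audio_io.inspirations(phases))

    rows = []
    for patient, entry in sorted(per_patient.items()):
        if not entry["recordings"]:
            continue
        events = (pd.concat(entry["events"], ignore_index=True)
                  if entry["events"] else pd.DataFrame(
                      columns=["inspiration", "relative_onset", "is_fine",
                               "tcd_ms", "idw_ms", "ldw_ms", "a2_a1",
                               "a3_a1"]))
        agg = crackle_features.aggregate_patient(
            events, entry["n_insp"], count_fine_only=config.count_fine_only,
            onset_rule=config.onset_rule)
        pf = spectral_features.patient_percentiles(
            entry["recordings"], entry["phases"], config.spectral)
        rows.append({"patient_id": patient, **agg,
                     "f50_hz": pf.f50_hz, "f95_hz": pf.f95_hz,
                     "f99_hz": pf.f99_hz})
    features = pd.DataFrame(rows)
    features.to_csv(out / "features.csv", index=False, float_format="%.9f")
    (out / "extract_log.json").write_text(
        json.dumps(extraction_log, indent=1, sort_keys=True) + "\n")
    n_failed = sum(1 for v in extraction_log.values()
                   if v["status"] == "failed")
    if n_failed == len(extraction_log):
        raise RuntimeError("every recording failed extraction")
    return features


# ---------------------------------------------------------------------------
# analyze

#: display formats for the group-comparison table
_SUMMARY_VARS = ("age_y", "count_per_insp", "f99_hz", "f95_hz", "f50_hz",
                 "tcd_ms", "idw_ms", "ldw_ms", "a2_a1", "a3_a1")


def _term_rows(fit: si.LogisticFit) -> list[dict]:
    return [{"variable": t.name, "unit_scale": t.unit_scale,
             "or": t.or_value, "ci_low": t.ci_low, "ci_high": t.ci_high,
             "p": t.p} for t in fit.terms]


def cmd_analyze(config: PipelineConfig, features, out_dir) -> dict:
    """Run the full statistical chain on a feature table.

    ``features`` is a DataFrame or CSV path with a ``group`` column
    (honeycombing / non_honeycombing) plus the acoustic feature columns.
    Writes ``results.json`` and per-table CSVs; returns the results bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = (pd.read_csv(features) if not isinstance(features, pd.DataFrame)
          else features.copy())
    if df["group"].nunique() < 2:
        raise ValueError("outcome has a single class; nothing to contrast")
    df["honeycombing"] = (df["group"] == "honeycombing").astype(int)
    if "onset_tercile" in df:
        df["timing_early"] = (df["onset_tercile"] == "early").astype(float)

    hc = df[df["honeycombing"] == 1]
    non = df[df["honeycombing"] == 0]

    summary_rows = []
    for var in _SUMMARY_VARS:
        if var not in df or df[var].dropna().empty:
            continue
        x, y = hc[var].dropna(), non[var].dropna()
        if x.empty or y.empty:
            continue
        _, p = si.mann_whitney(x, y)
        summary_rows.append({
            "variable": var,
            "honeycombing": si.format_median_iqr(x),
            "non_honeycombing": si.format_median_iqr(y),
            "p": p})
    timing_table = None
    if "onset_tercile" in df:
        counts = pd.crosstab(df["group"], df["onset_tercile"])
        counts = counts.reindex(index=["honeycombing", "non_honeycombing"],
                                columns=["early", "mid", "late"],
                                fill_value=0)
        nonzero_cols = counts.loc[:, counts.sum(axis=0) > 0]
        stat, dof, p = si.chi_squared(nonzero_cols.to_numpy())
        timing_table = {"counts": counts.to_dict(), "chi2": stat,
                        "df": dof, "p": p}

    model = config.model
    candidates = [si.TermSpec(n, s) for n, s in model.candidates.items()
                  if n in df.columns]
    univariate = {}
    for t in candidates:
        fit = si.fit_logistic(df, "honeycombing", [t])
        univariate[t.name] = {"converged": fit.converged,
                              "n_used": fit.n_used,
                              **_term_rows(fit)[0]}

    selected = si.select_multivariate_terms(
        df, "honeycombing", candidates, p_enter=model.p_enter,
        corr_threshold=model.corr_threshold,
        representatives=model.representatives)
    forced = [si.TermSpec(n, s) for n, s in model.forced_terms.items()
              if n in df.columns and all(t.name != n for t in selected)]
    multi_terms = selected + forced
    multivariate = None
    if selected:
        fit = si.fit_logistic(df, "honeycombing", multi_terms)
        multivariate = {"converged": fit.converged, "n_used": fit.n_used,
                        "terms": _term_rows(fit)}

    roc = {}
    for var in model.roc_variables:
        if var not in df.columns:
            continue
        sub = df[[var, "honeycombing"]].dropna()
        r = si.roc_analysis(sub[var], sub["honeycombing"])
        ci_lo, ci_hi = si.auc_bootstrap_ci(
            sub[var].to_numpy(), sub["honeycombing"].to_numpy(),
            seed=config.seed)
        roc[var] = {"auc": r.auc, "cutoff": r.cutoff,
                    "sens": r.cutoff_sens, "spec": r.cutoff_spec,
                    "auc_ci_low": ci_lo, "auc_ci_high": ci_hi,
                    "points": {"fpr": (1 - r.spec).tolist(),
                               "tpr": r.sens.tolist()}}

    dichotomized = None
    if roc:
        d = df
        terms = []
        for var, r in roc.items():
            name = f"{var}_ge_cutoff"
            d = si.dichotomize(d, var, r["cutoff"], new_name=name)
            terms.append(si.TermSpec(name, 1.0))
        if "timing_early" in d:
            terms.append(si.TermSpec("timing_early", 1.0))
        fit = si.fit_logistic(d, "honeycombing", terms)
        dichotomized = {"converged": fit.converged, "n_used": fit.n_used,
                        "cutoffs": {v: roc[v]["cutoff"] for v in roc},
                        "terms": _term_rows(fit)}

    results = {
        "n": {"honeycombing": int(len(hc)), "non_honeycombing": int(len(non))},
        "group_summaries": summary_rows,
        "onset_timing": timing_table,
        "univariate": univariate,
        "selected_terms": [t.name for t in selected],
        "multivariate": multivariate,
        "roc": roc,
        "dichotomized": dichotomized,
    }
    (out / "results.json").write_text(
        json.dumps(results, indent=1, sort_keys=True, default=float) + "\n")
    pd.DataFrame(summary_rows).to_csv(out / "table_group_comparison.csv",
                                      index=False)
    if multivariate:
        pd.DataFrame(multivariate["terms"]).to_csv(
            out / "table_multivariate.csv", index=False)
    if dichotomized:
        pd.DataFrame(dichotomized["terms"]).to_csv(
            out / "table_dichotomized.csv", index=False)
    return results


# ---------------------------------------------------------------------------
# report

def _fmt_or_row(t: dict) -> str:
    return (f"| {t['variable']} | {t['or']:.3f} | "
            f"{t['ci_low']:.3f}–{t['ci_high']:.3f} | {t['p']:.3f} |")


def cmd_report(results, out_dir) -> Path:
    """Render a results bundle (dict or results.json path) as markdown
    plus a ROC plot.  The reporter formats; it never computes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(results, dict):
        results = json.loads(Path(results).read_text())

    lines = ["# Crackle analysis report", ""]
    n = results["n"]
    lines += [f"Honeycombing n = {n['honeycombing']}, "
              f"non-honeycombing n = {n['non_honeycombing']}", ""]

    lines += ["## Group comparison (median [IQR], Mann-Whitney P)", "",
              "| Variable | Honeycombing | Non-honeycombing | P |",
              "|---|---|---|---|"]
    for row in results["group_summaries"]:
        lines.append(f"| {row['variable']} | {row['honeycombing']} | "
                     f"{row['non_honeycombing']} | {row['p']:.3f} |")
    if results.get("onset_timing"):
        t = results["onset_timing"]
        lines += ["", f"Onset timing chi-squared = {t['chi2']:.2f} "
                  f"(df {t['df']}), P = {t['p']:.4g}"]

    if results.get("multivariate"):
        lines += ["", "## Multivariate logistic regression", "",
                  "| Variable | OR | 95% CI | P |", "|---|---|---|---|"]
        lines += [_fmt_or_row(t) for t in results["multivariate"]["terms"]]

    if results.get("roc"):
        lines += ["", "## ROC cutoffs (upper-left corner)", "",
                  "| Variable | AUC | Cutoff | Sens | Spec |",
                  "|---|---|---|---|---|"]
        fig, ax = plt.subplots(figsize=(5, 5))
        for var, r in results["roc"].items():
            lines.append(f"| {var} | {r['auc']:.3f} | {r['cutoff']:.1f} | "
                         f"{100 * r['sens']:.1f}% | {100 * r['spec']:.1f}% |")
            pts = r["points"]
            order = np.argsort(pts["fpr"])
            ax.plot(np.asarray(pts["fpr"])[order],
                    np.asarray(pts["tpr"])[order],
                    label=f"{var} (AUC {r['auc']:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        fig.savefig(out / "roc.png", dpi=100)
        plt.close(fig)
        lines += ["", "![ROC curves](roc.png)"]

    if results.get("dichotomized"):
        lines += ["", "## Logistic regression at the ROC cutoffs", "",
                  "| Variable | OR | 95% CI | P |", "|---|---|---|---|"]
        lines += [_fmt_or_row(t) for t in results["dichotomized"]["terms"]]

    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
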