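"""End-to-end orchestration: simulate -> preprocess -> cluster -> statistics
-> decoding -> ECoG state -> EPSP metrics, with QC-based inclusion and
provenance tracking.

``run_all`` executes every stage on simulated sessions and returns a
``RunReport``; ``summarize`` condenses it into the two standard summary
tables (per-pattern clustering/decoding performance, and single-pulse EPSP
statistics)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import brainstate, decoding, epsp, kwstats
from .clustering import ClusterParams, ResponseTypeResults, cluster_responses
from .patterns import PATTERN_LABELS, generate_patterns
from .preprocessing import (blank_artifacts, extract_windows, normalize_windows,
                            qc_check, remove_spikes, smooth_trace)
from .simulate import SessionConfig, simulate_session

TABLE1_COLUMN_NAMES = {"Finf": "F_inf", "Sinf": "S_inf"}


@dataclass(frozen=True)
class PipelineConfig:
    n_neurons: int = 13
    session: SessionConfig = field(default_factory=SessionConfig)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    alpha: float = 0.05
    n_shuffles: int = 20
    decode_iters: int = 40
    run_stats: bool = True
    run_decoding: bool = True
    run_ecog: bool = True
    run_epsp: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class CellResult:
    neuron: int
    pattern: str
    n_windows: int
    typeset: ResponseTypeResults
    windows_ext: np.ndarray
    onsets_s: np.ndarray
    accuracy: float = np.nan
    f1_ungrouped: float = np.nan


@dataclass
class RunReport:
    config: PipelineConfig
    cells: list[CellResult]
    excluded: list[tuple[int, str]]
    fraction_curve: np.ndarray | None
    null_curve: np.ndarray | None
    state_association: brainstate.StateAssociation | None
    single_pulse_table: pd.DataFrame | None
    order_effect_p: list[np.ndarray]
    provenance: dict

    def cell_frame(self) -> pd.DataFrame:
        rows = [(c.neuron, c.pattern, c.n_windows, c.typeset.n_types,
                 c.accuracy, c.typeset.ungrouped_fraction, c.f1_ungrouped)
                for c in self.cells]
        return pd.DataFrame(rows, columns=[
            "neuron", "pattern", "n_windows", "n_types",
            "accuracy", "fraction_ungrouped", "f1_ungrouped"])


def _preprocess_neuron(rec, patterns):
    """Smooth, blank artifacts, QC, remove spikes; return cleaned vm + QC."""
    fs = rec.fs_vm
    pulse_times = []
    pat_by_label = {p.label: p for p in patterns}
    for _, row in rec.events.iterrows():
        if row.kind == "single":
            pulse_times.append(row.onset_s)
        else:
            p = pat_by_label[row.label]
            pulse_times += [row.onset_s + off / 1000.0 for off, _ in p.pulses()]
    vm = smooth_trace(rec.vm, fs)
    vm = blank_artifacts(vm, np.asarray(pulse_times), fs)
    qc = qc_check(vm, fs)
    vm, spike_times = remove_spikes(vm, fs)
    return vm, qc, np.sort(np.asarray(pulse_times)), spike_times


def _decode_cell(ts: ResponseTypeResults, n_iter: int, seed: int) -> tuple[float, float]:
    """Within-pattern decoding accuracy and ungrouped F1 (NaN when undefined)."""
    try:
        res = decoding.decode_typesets([ts], "within_pattern",
                                       n_iter=n_iter, seed=seed)
    except ValueError:
        return np.nan, np.nan
    acc = res.accuracy
    f1_un = np.nan
    for name, f1 in zip(res.classes, res.f1):
        if name == "ungrouped":
            f1_un = float(f1)
    return float(acc), f1_un


def run_all(config: PipelineConfig | None = None) -> RunReport:
    """Execute the full pipeline on simulated sessions."""
    cfg = config or PipelineConfig()
    base = cfg.session
    patterns = generate_patterns(base.n_patterns, base.n_channels, seed=base.seed)
    cells: list[CellResult] = []
    excluded: list[tuple[int, str]] = []
    ecog_cells = []
    sp_rows = []
    order_mats = []

    for neuron in range(cfg.n_neurons):
        scfg = replace(base, neuron_id=neuron)
        rec, truth = simulate_session(scfg)
        vm, qc, pulse_times, _ = _preprocess_neuron(rec, patterns)
        if not qc.overall:
            excluded.append((neuron, "failed QC: " + ", ".join(
                k for k, v in qc.passes.items() if not v)))
            continue
        fs = rec.fs_vm
        raw350, meta = extract_windows(vm, fs, rec.events, 350.0)
        raw1200, meta1200 = extract_windows(vm, fs, rec.events, 1200.0)
        track = None
        if cfg.run_ecog and scfg.include_ecog and rec.ecog.size:
            track = brainstate.segment_ecog(rec.ecog, rec.fs_ecog)
        for label in meta.label.unique():
            sel = (meta.label == label).to_numpy()
            w350, degen = normalize_windows(raw350[sel], fs)
            # extended windows exist only for repetitions not cut off at the end
            sel_ext = (meta1200.label == label).to_numpy()
            wext, _ = normalize_windows(raw1200[sel_ext], fs)
            ts = cluster_responses(w350, cfg.cluster, degen,
                                   neuron_id=neuron, pattern_label=label)
            onsets = meta.loc[sel, "onset_s"].to_numpy()
            cell = CellResult(neuron, label, w350.shape[0], ts, wext, onsets)
            if cfg.run_decoding:
                cell.accuracy, cell.f1_ungrouped = _decode_cell(
                    ts, cfg.decode_iters, seed=cfg.seed + 13 * neuron)
            cells.append(cell)
            if track is not None:
                ecog_cells.append((ts, brainstate.state_at_times(track, onsets)))
        if cfg.run_epsp:
            sp_rows += _single_pulse_stage(vm, fs, rec, neuron, order_mats)

    fraction_curve = null_curve = None
    if cfg.run_stats and cells:
        tcs = []
        kw_cells = []
        for c in cells:
            n_ext = c.windows_ext.shape[0]
            labels = c.typeset.labels[:n_ext]
            tcs.append(kwstats.type_specificity_timecourse(c.windows_ext, labels, cfg.alpha))
            kw_cells.append((c.windows_ext, labels))
        try:
            fraction_curve = kwstats.significant_fraction(tcs, cfg.alpha)
            null_curve, _ = kwstats.shuffle_control(
                kw_cells, cfg.n_shuffles, seed=cfg.seed, alpha=cfg.alpha)
        except ValueError:
            pass

    assoc = None
    if cfg.run_ecog and ecog_cells:
        try:
            assoc = brainstate.type_state_association(ecog_cells)
        except ValueError:
            pass

    sp_table = pd.DataFrame(sp_rows, columns=[
        "neuron", "channel", "rank", "amplitude_mv", "latency_ms", "ttp_ms"]) \
        if sp_rows else None

    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_neurons_included": cfg.n_neurons - len(excluded),
    }
    return RunReport(cfg, cells, excluded, fraction_curve, null_curve,
                     assoc, sp_table, order_mats, provenance)


def _single_pulse_stage(vm, fs, rec, neuron, order_mats) -> list[tuple]:
    """Measure isolated single-pulse responses; run the order-effect test."""
    rows = []
    singles = rec.events[rec.events.kind == "single"]
    per_channel: dict[int, list] = {}
    pulses_per_chunk = 5
    for _, row in singles.iterrows():
        ev = epsp.measure_pulse_response(vm, row.onset_s, fs)
        if ev is None:
            continue
        rank = int(row.repetition) % pulses_per_chunk + 1
        rows.append((neuron, int(row.channel), rank,
                     ev.amplitude_mv, ev.latency_ms, ev.ttp_ms))
        per_channel.setdefault(int(row.channel), []).append((rank, ev.amplitude_mv))
    for ch, vals in sorted(per_channel.items()):
        df = pd.DataFrame(vals, columns=["rank", "amplitude_mv"])
        order_mats.append(epsp.order_effect_test(df, n_ranks=pulses_per_chunk))
    return rows


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

def summarize(report: RunReport) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-pattern mean (SD) performance table and single-pulse statistics.

    The first table has one column per stimulation pattern plus a grand
    average (arithmetic mean over included cells); rows are the number of
    identified types, within-pattern separation accuracy, ungrouped
    fraction, and the ungrouped F1 score.
    """
    cells = report.cell_frame()
    if cells.empty:
        raise ValueError("no completed cells to summarize")
    metrics = [
        ("Identified response types (N)", "n_types", 1.0),
        ("Type separation accuracy (%)", "accuracy", 100.0),
        ("Fraction ungrouped (%)", "fraction_ungrouped", 100.0),
        ("F1-score, ungrouped (0-1)", "f1_ungrouped", 1.0),
    ]
    labels = [l for l in PATTERN_LABELS if l in set(cells.pattern)]
    labels += [l for l in cells.pattern.unique() if l not in labels]
    columns = ["Grand average"] + [TABLE1_COLUMN_NAMES.get(l, l) for l in labels]
    out = {}
    for name, col, scale in metrics:
        vals = []
        g = cells[col] * scale
        vals.append(_mean_sd(g))
        for label in labels:
            vals.append(_mean_sd(cells.loc[cells.pattern == label, col] * scale))
        out[name] = vals
    table1 = pd.DataFrame(out, index=columns).T
    table1.columns = columns

    table2 = None
    if report.single_pulse_table is not None and len(report.single_pulse_table):
        sp = report.single_pulse_table
        rows = {}
        for metric, col in [("Peak amplitude", "amplitude_mv"),
                            ("Response onset latency time", "latency_ms"),
                            ("Latency to peak", "ttp_ms")]:
            pooled = sp[col]
            per_neuron_cv = sp.groupby("neuron")[col].apply(
                lambda x: x.std(ddof=1) / x.mean() if len(x) > 1 else np.nan)
            rows[metric] = {
                "pooled_mean": float(pooled.mean()),
                "pooled_sd": float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0,
                "cv_mean": float(per_neuron_cv.mean()),
                "cv_sd": float(per_neuron_cv.std(ddof=1)) if per_neuron_cv.notna().sum() > 1 else 0.0,
            }
        table2 = pd.DataFrame(rows).T
    return table1, table2


def _mean_sd(x: pd.Series) -> str:
    x = x.dropna()
    if x.empty:
        return "n/a"
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    return f"{x.mean():.1f} ({sd:.1f})"
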