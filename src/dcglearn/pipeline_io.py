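"""Panel I/O, experiment configuration, and replicated-experiment drivers."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dcglearn.graphs import WeightedDigraph
from dcglearn.infer import McmcControl, PosteriorSummary, PriorConfig, run_mcmc, select_graph
from dcglearn.simulate import PanelData, scenario_one, scenario_two

__all__ = [
    "ExperimentConfig",
    "ReplicationReport",
    "read_panel",
    "write_panel",
    "run_replicated_experiment",
    "render_report",
]


def write_panel(panel: PanelData, path, truth: WeightedDigraph | None = None, meta: dict | None = None) -> None:
    """Write a panel as long-format CSV; optional JSON sidecar with metadata."""
    path = Path(path)
    # %.17g guarantees float64 round-trip through text
    panel.frame.to_csv(path, index=False, float_format="%.17g")
    if truth is not None or meta is not None:
        sidecar = {}
        if truth is not None:
            sidecar["truth"] = {
                "labels": list(truth.labels),
                "weights": truth.weights.tolist(),
            }
        if meta:
            sidecar.update(meta)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_panel(path, min_visits: int = 2, on_gap: str = "error") -> PanelData:
    """Read and validate a long-format panel CSV.

    Requires ``id``, ``visit``, and at least one ``Y*`` column.  Individuals
    with fewer than ``min_visits`` visits are dropped with a warning.  Rows
    are canonically sorted, so input row order is irrelevant.  Visits within
    an individual must be consecutive from 1 (``on_gap="error"``) or the
    individual is dropped (``on_gap="drop"``).
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = {"id", "visit"} - set(frame.columns)
    if missing:
        raise ValueError(f"panel file missing required columns {sorted(missing)}")
    value_cols = [c for c in frame.columns if c.startswith(("Y", "X"))]
    if not any(c.startswith("Y") for c in value_cols):
        raise ValueError("panel file has no outcome (Y*) columns")
    bad = [c for c in value_cols if not pd.api.types.is_numeric_dtype(frame[c])]
    if bad:
        rows = frame[pd.to_numeric(frame[bad[0]], errors="coerce").isna()].index[:3].tolist()
        raise ValueError(f"non-numeric values in column {bad[0]} (rows {rows})")
    frame = frame.sort_values(["id", "visit"], kind="mergesort")
    keep_ids = []
    for uid, grp in frame.groupby("id", sort=False):
        if len(grp) < min_visits:
            warnings.warn(f"dropping individual {uid!r}: fewer than {min_visits} visits")
            continue
        visits = grp["visit"].to_numpy()
        if not np.array_equal(visits, np.arange(1, len(visits) + 1)):
            if on_gap == "drop":
                warnings.warn(f"dropping individual {uid!r}: non-consecutive visits")
                continue
            raise ValueError(f"individual {uid!r} has non-consecutive visits")
        keep_ids.append(uid)
    frame = frame[frame["id"].isin(keep_ids)].reset_index(drop=True)
    if frame.empty:
        raise ValueError("no individuals left after validation")
    return PanelData(frame)


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings for a replicated simulate-fit-select experiment."""

    scenario: int = 1
    n_individuals: int = 1000
    instrument_type: str = "covariate"  # scenario 1
    eta: float = 1.0                    # scenario 2
    priors: PriorConfig = field(default_factory=PriorConfig)
    control: McmcControl = field(default_factory=McmcControl)
    n_replicates: int = 1
    master_seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.scenario not in (1, 2):
            raise ValueError("scenario must be 1 or 2")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "scenario": self.scenario,
                "n_individuals": self.n_individuals,
                "instrument_type": self.instrument_type,
                "eta": self.eta,
                "priors": vars(self.priors),
                "control": {
                    k: v for k, v in vars(self.control).items()
                },
                "n_replicates": self.n_replicates,
                "master_seed": self.master_seed,
                "threshold": self.threshold,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _edge_key(summary: PosteriorSummary) -> tuple:
    """Graph-mode identity: instantaneous + lagged edge support, weights ignored."""
    return (tuple(sorted(summary.edges_B)), tuple(sorted(summary.edges_A)))


@dataclass
class ReplicationReport:
    config: ExperimentConfig
    mode_counts: dict  # edge-support key -> count
    mode_examples: dict  # edge-support key -> PosteriorSummary
    edge_counts_B: np.ndarray  # (Ly+1, Q, Q) marginal detection counts
    edge_counts_A: np.ndarray
    seeds: list[int]

    @property
    def n_replicates(self) -> int:
        return sum(self.mode_counts.values())

    def mode_frequencies(self) -> list[tuple[tuple, float]]:
        n = self.n_replicates
        return sorted(
            ((k, c / n) for k, c in self.mode_counts.items()),
            key=lambda kv: -kv[1],
        )

    def edge_detection_rate(self, lag: int, p: int, q: int, either_direction: bool = False) -> float:
        """Marginal relative frequency of the outcome edge ``p -> q`` at ``lag``."""
        n = self.n_replicates
        rate = self.edge_counts_B[lag, q, p] / n
        if either_direction and lag == 0:
            both = sum(
                1
                for key in self._replicate_keys
                if (0, p, q) in key[0] or (0, q, p) in key[0]
            )
            rate = both / n
        return float(rate)


def run_replicated_experiment(config: ExperimentConfig) -> ReplicationReport:
    """Per-replicate simulate -> fit -> select pipeline.

    Replicate seeds are derived from the master seed via a splittable seed
    sequence, so results are reproducible regardless of execution order.
    """
    seed_seq = np.random.SeedSequence(config.master_seed)
    children = seed_seq.spawn(config.n_replicates)
    mode_counts: dict = {}
    mode_examples: dict = {}
    edge_counts_B = None
    edge_counts_A = None
    replicate_keys = []
    seeds = []
    for r, child in enumerate(children):
        rep_seed = int(child.generate_state(1)[0])
        seeds.append(rep_seed)
        try:
            if config.scenario == 1:
                res = scenario_one(
                    config.n_individuals, config.instrument_type, seed=rep_seed
                )
            else:
                res = scenario_two(config.eta, config.n_individuals, seed=rep_seed)
            chains = run_mcmc(
                res.panel,
                config.priors,
                McmcControl(
                    **{
                        **vars(config.control),
                        "seed": rep_seed,
                    }
                ),
            )
            summary = select_graph(chains, config.threshold)
        except Exception as exc:  # pragma: no cover - error propagation contract
            raise RuntimeError(f"replicate {r} failed") from exc
        key = _edge_key(summary)
        replicate_keys.append(key)
        mode_counts[key] = mode_counts.get(key, 0) + 1
        mode_examples.setdefault(key, summary)
        if edge_counts_B is None:
            edge_counts_B = np.zeros_like(summary.incl_B)
            edge_counts_A = np.zeros_like(summary.incl_A)
        for lag, p, q in summary.edges_B:
            edge_counts_B[lag, q, p] += 1
        for lag, s, q in summary.edges_A:
            edge_counts_A[lag, q, s] += 1
    report = ReplicationReport(
        config=config,
        mode_counts=mode_counts,
        mode_examples=mode_examples,
        edge_counts_B=edge_counts_B,
        edge_counts_A=edge_counts_A,
        seeds=seeds,
    )
    report._replicate_keys = replicate_keys
    return report


def render_report(report: ReplicationReport, out_dir) -> list[Path]:
    """Write graph figures (DOT), frequency tables (CSV), and a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    freq_path = out / "graph_frequencies.csv"
    lines = ["mode,count,frequency,edges_B,edges_A"]
    for rank, (key, freq) in enumerate(report.mode_frequencies(), start=1):
        count = report.mode_counts[key]
        eb = ";".join(f"l{l}:{p}->{q}" for l, p, q in key[0])
        ea = ";".join(f"l{l}:X{s + 1}->{q}" for l, s, q in key[1])
        lines.append(f"{rank},{count},{freq:.4f},{eb},{ea}")
    freq_path.write_text("\n".join(lines) + "\n")
    written.append(freq_path)

    for rank, (key, _freq) in enumerate(report.mode_frequencies(), start=1):
        summary = report.mode_examples[key]
        graph = _summary_digraph(summary)
        dot_path = out / f"mode_{rank}.dot"
        dot_path.write_text(graph)
        written.append(dot_path)

    json_path = out / "report.json"
    json_path.write_text(
        json.dumps(
            {
                "package_version": _package_version(),
                "config_hash": report.config.config_hash(),
                "master_seed": report.config.master_seed,
                "n_replicates": report.n_replicates,
                "seeds": report.seeds,
                "modes": [
                    {"count": report.mode_counts[k], "frequency": f, "edges_B": [list(e) for e in k[0]], "edges_A": [list(e) for e in k[1]]}
                    for k, f in report.mode_frequencies()
                ],
                "edge_counts_B": report.edge_counts_B.tolist(),
                "edge_counts_A": report.edge_counts_A.tolist(),
            },
            indent=2,
        )
    )
    written.append(json_path)
    return written


def _package_version() -> str:
    import dcglearn

    return dcglearn.__version__


def _summary_digraph(summary: PosteriorSummary) -> str:
    """DOT rendering of a selected graph, edge labels = posterior means (2 dp)."""
    lines = ["digraph selected {"]
    Q = summary.coef_B.shape[1]
    for q in range(Q):
        lines.append(f'  "Y{q + 1}";')
    for lag, p, q in summary.edges_B:
        w = summary.coef_B[lag, q, p]
        src = f"Y{p + 1}" if lag == 0 else f"Y{p + 1}[-{lag}]"
        lines.append(f'  "{src}" -> "Y{q + 1}" [label="{w:.2f}"];')
    for lag, s, q in summary.edges_A:
        w = summary.coef_A[lag, q, s]
        src = f"X{s + 1}" if lag == 0 else f"X{s + 1}[-{lag}]"
        lines.append(f'  "{src}" -> "Y{q + 1}" [label="{w:.2f}", style=dashed];')
    lines.append("}")
    return "\n".join(lines) + "\n"
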