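"""Run orchestration: reconstruction -> MAP ranges -> events -> rates -> LTT.

A :class:`RunConfig` (read from a YAML file) names the inputs, the MCMC
block, the rate-window block with optional named periods, and clade
definitions for LTT curves.  Commands write their artifacts atomically
(temp file + rename), stamp every table header with the config hash and
seed, and log to both console and a run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import bbm, events_rates, synth, treedata

logger = logging.getLogger("bbmrange")


@dataclass(frozen=True)
class Period:
    label: str
    old: float
    young: float

    def __post_init__(self):
        if not self.old > self.young:
            raise ValueError(f"period {self.label!r} must have old > young")


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    tree: Path
    codings: Path
    out: Path
    alphabet: treedata.AreaAlphabet
    bbm: bbm.BBMConfig = field(default_factory=bbm.BBMConfig)
    window: float = events_rates.DEFAULT_WINDOW
    cone: float = events_rates.DEFAULT_CONE
    t_max: float | None = None
    t_min: float = 0.0
    periods: tuple[Period, ...] = ()
    clades: Mapping[str, Sequence[str]] = field(default_factory=dict)
    plot: bool = False

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        base = Path(path).parent
        bbm_block = raw.get("bbm", {})
        rates_block = raw.get("rates", {})
        periods = tuple(
            Period(p["label"], float(p["old"]), float(p["young"]))
            for p in rates_block.get("periods", [])
        )
        cfg = cls(
            tree=_resolve(base, raw["tree"]),
            codings=_resolve(base, raw["codings"]),
            out=_resolve(base, raw.get("out", "out")),
            alphabet=treedata.AreaAlphabet.from_string(raw.get("alphabet", "ABCDEFGHIJ")),
            bbm=bbm.BBMConfig(
                generations=int(bbm_block.get("generations", 100_000)),
                burnin=int(bbm_block.get("burnin", 20_000)),
                samplefreq=int(bbm_block.get("samplefreq", 100)),
                chains=int(bbm_block.get("chains", 10)),
                max_areas=int(bbm_block.get("max_areas", 3)),
                seed=int(bbm_block.get("seed", 0)),
            ),
            window=float(rates_block.get("window", events_rates.DEFAULT_WINDOW)),
            cone=float(rates_block.get("cone", events_rates.DEFAULT_CONE)),
            t_max=rates_block.get("t_max"),
            t_min=float(rates_block.get("t_min", 0.0)),
            periods=periods,
            clades={str(k): list(v) for k, v in raw.get("clades", {}).items()},
            plot=bool(raw.get("plot", False)),
        )
        for p in (cfg.tree, cfg.codings):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        return cfg

    def config_hash(self) -> str:
        payload = {
            "tree": str(self.tree),
            "codings": str(self.codings),
            "alphabet": "".join(self.alphabet.letters),
            "bbm": {
                "generations": self.bbm.generations,
                "burnin": self.bbm.burnin,
                "samplefreq": self.bbm.samplefreq,
                "chains": self.bbm.chains,
                "max_areas": self.bbm.max_areas,
                "seed": self.bbm.seed,
            },
            "window": self.window,
            "cone": self.cone,
            "t_max": self.t_max,
            "t_min": self.t_min,
            "periods": [(p.label, p.old, p.young) for p in self.periods],
            "clades": {k: list(v) for k, v in self.clades.items()},
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _resolve(base: Path, p) -> Path:
    p = Path(p)
    return p if p.is_absolute() else base / p


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.setLevel(logging.INFO)
    target = str((out_dir / "run.log").resolve())
    for h in list(logger.handlers):
        if isinstance(h, logging.FileHandler) and h.baseFilename != target:
            logger.removeHandler(h)
            h.close()
    if not any(
        isinstance(h, logging.FileHandler) and h.baseFilename == target for h in logger.handlers
    ):
        fh = logging.FileHandler(target)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) and not isinstance(h, logging.FileHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(sh)


def _write_atomic(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _frame_text(df: pd.DataFrame, header_lines: Sequence[str]) -> str:
    head = "".join(f"# {line}\n" for line in header_lines)
    return head + df.to_csv(sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    """Read back any table written by this pipeline."""
    return pd.read_csv(path, sep="\t", comment="#")


def cmd_reconstruct(config: RunConfig) -> dict[str, Path]:
    """Run the MCMC reconstruction and write its artifact set.

    Artifacts: ``range_posteriors.tsv`` (node, range, probability),
    ``annotated.nwk`` (MAP range + top-3 posterior entries per node),
    ``trace.tsv`` (pooled MCMC samples), ``run.log``.
    """
    out = Path(config.out)
    _setup_logging(out)
    h = config.config_hash()
    logger.info("reconstruct: config_hash=%s seed=%d", h, config.bbm.seed)
    logger.info(
        "bbm settings: generations=%d burnin=%d samplefreq=%d chains=%d max_areas=%d",
        config.bbm.generations,
        config.bbm.burnin,
        config.bbm.samplefreq,
        config.bbm.chains,
        config.bbm.max_areas,
    )
    chron = treedata.parse_chronogram(Path(config.tree).read_text())
    coding = treedata.read_region_codings(Path(config.codings).read_text(), config.alphabet)
    treedata.validate_pair(chron, coding)
    result = bbm.run_bbm_mcmc(chron, coding, config.bbm, config.alphabet)
    logger.info(
        "pooled %d samples (%d chains x %d); acceptance=%s",
        len(result.samples),
        config.bbm.chains,
        config.bbm.samples_per_chain,
        {c: {k: round(v, 3) for k, v in r.items()} for c, r in result.acceptance.items()},
    )
    header = [f"config_hash={h}", f"seed={config.bbm.seed}"]
    written: dict[str, Path] = {}
    try:
        written["trace"] = out / "trace.tsv"
        _write_atomic(written["trace"], _frame_text(result.samples, header))
        written["range_posteriors"] = out / "range_posteriors.tsv"
        post = result.range_posterior_frame()
        post = post[post["probability"] >= 1e-9]
        _write_atomic(written["range_posteriors"], _frame_text(post, header))
        written["annotated_tree"] = out / "annotated.nwk"
        _write_atomic(written["annotated_tree"], _annotated_newick(chron, result) + "\n")
    except BaseException:
        for p in written.values():
            if p.exists():
                p.unlink()
        raise
    logger.info("reconstruct: wrote %s", sorted(p.name for p in written.values()))
    written["log"] = out / "run.log"
    return written


def _annotated_newick(chron: treedata.Chronogram, result: bbm.BBMResult) -> str:
    annotations = {}
    maps = result.map_ranges()
    for v in range(chron.n_nodes):
        post = result.range_posteriors[v]
        top = sorted(
            post.items(), key=lambda kv: (-kv[1], len(kv[0]), result.alphabet.range_key(kv[0]))
        )[:3]
        top_str = "/".join(
            f"{result.alphabet.format_range(rng)}:{p:.4f}" for rng, p in top
        )
        annotations[v] = (
            f"&range={result.alphabet.format_range(maps[v])},top={top_str}"
        )
    return chron.to_newick(annotations=annotations)


def read_map_assignment(path, alphabet: treedata.AreaAlphabet):
    """Parse an annotated newick back into (chronogram, node->MAP range)."""
    chron, notes = treedata.parse_annotated_chronogram(Path(path).read_text())
    assign: dict[int, frozenset] = {}
    for v, ann in notes.items():
        if "range" in ann:
            assign[v] = frozenset(str(ann["range"]).split("|"))
    missing = [v for v in range(chron.n_nodes) if v not in assign]
    if missing:
        raise events_rates.AssignmentError(
            f"annotated tree is missing MAP ranges on nodes {missing[:5]}..."
            if len(missing) > 5
            else f"annotated tree is missing MAP ranges on nodes {missing}"
        )
    return chron, assign


def cmd_rates(config: RunConfig, annotated_tree) -> dict[str, Path]:
    """Turn an annotated tree into events, rate series, period summary, LTT.

    The period summary lists, per named period and event kind, the
    mean-of-windows rate, the pooled-count rate, and per-region/per-route
    event tallies (origination circles and transition arrows).
    """
    out = Path(config.out)
    _setup_logging(out)
    h = config.config_hash()
    header = [f"config_hash={h}", f"seed={config.bbm.seed}"]
    chron, assign = read_map_assignment(annotated_tree, config.alphabet)
    events = events_rates.extract_events(chron, assign)
    t_max = config.t_max if config.t_max is not None else chron.root_age
    series = {
        kind: events_rates.sliding_window_rates(
            events, chron, kind, width=config.window, t_max=t_max, t_min=config.t_min
        )
        for kind in ("transition", "origination")
    }
    written: dict[str, Path] = {}
    try:
        written["events"] = out / "events.tsv"
        _write_atomic(
            written["events"],
            _frame_text(events_rates.events_frame(events, config.alphabet), header),
        )
        for kind, s in series.items():
            key = f"rates_{kind}"
            written[key] = out / f"{key}.tsv"
            _write_atomic(written[key], _frame_text(s.to_frame(), header))
            cone = events_rates.cone_series(
                events, chron, kind, cone_width=config.cone,
                grid_step=config.window / 2, t_max=t_max, t_min=config.t_min,
            )
            ckey = f"cones_{kind}"
            written[ckey] = out / f"{ckey}.tsv"
            _write_atomic(written[ckey], _frame_text(cone, header))
        written["period_summary"] = out / "period_summary.tsv"
        _write_atomic(
            written["period_summary"],
            _frame_text(period_summary(series, events, config.periods), header),
        )
        ltt = events_rates.ltt_curve(chron)
        written["ltt"] = out / "ltt.tsv"
        _write_atomic(written["ltt"], _frame_text(ltt.to_frame(), header))
        for label, taxa in config.clades.items():
            curve = events_rates.ltt_curve(chron, mrca_of=taxa)
            key = f"ltt_{label}"
            written[key] = out / f"{key}.tsv"
            _write_atomic(written[key], _frame_text(curve.to_frame(), header))
        if config.plot:
            written.update(_plots(out, series, events, chron, config))
    except BaseException:
        for p in written.values():
            if p.exists():
                p.unlink()
        raise
    logger.info("rates: wrote %s", sorted(p.name for p in written.values()))
    return written


def period_summary(
    series: Mapping[str, events_rates.RateSeries],
    events: Sequence[events_rates.EventRecord],
    periods: Sequence[Period],
) -> pd.DataFrame:
    rows = []
    for period in periods:
        for kind, s in series.items():
            sel = [
                e for e in events
                if e.kind == kind and period.old >= e.time > period.young
            ]
            mean = events_rates.period_mean_rate(s, period.old, period.young)
            pooled = events_rates.period_mean_rate(s, period.old, period.young, pooled=True)
            if kind == "origination":
                tally: dict[str, int] = {}
                for e in sel:
                    key = "|".join(sorted(e.region))
                    tally[key] = tally.get(key, 0) + 1
            else:
                tally = {}
                for e in sel:
                    key = "|".join(sorted(e.from_range)) + "->" + "|".join(sorted(e.to_range))
                    tally[key] = tally.get(key, 0) + 1
            tally_str = ";".join(f"{k}:{v}" for k, v in sorted(tally.items()))
            rows.append(
                (period.label, period.old, period.young, kind, mean, pooled, len(sel), tally_str)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "period", "old_mya", "young_mya", "kind",
            "mean_rate", "pooled_rate", "events", "region_tallies",
        ],
    )


def _plots(out, series, events, chron, config) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    for ax, (kind, s) in zip(axes, series.items()):
        ax.step(s.old_edges, s.values, where="post", label=f"{kind} (windows)")
        cone = events_rates.cone_series(
            events, chron, kind, cone_width=config.cone,
            grid_step=config.window / 2,
            t_max=config.t_max if config.t_max is not None else chron.root_age,
            t_min=config.t_min,
        )
        ax.plot(cone["age_mya"], cone["rate"], alpha=0.7, label=f"{kind} (cones)")
        ax.set_ylabel("events / lineage / Myr")
        ax.legend()
    axes[-1].set_xlabel("age (mya)")
    axes[-1].invert_xaxis()
    path = out / "rates.svg"
    fig.savefig(path)
    plt.close(fig)
    written["rates_plot"] = path

    ltt = events_rates.ltt_curve(chron)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.step(ltt.breaks[:-1], ltt.counts, where="post")
    ax.set_yscale("log")
    ax.set_xlabel("age (mya)")
    ax.set_ylabel("lineages")
    ax.invert_xaxis()
    path = out / "ltt.svg"
    fig.savefig(path)
    plt.close(fig)
    written["ltt_plot"] = path
    return written


def cmd_simulate(cfg: synth.SimConfig, out_dir) -> dict[str, Path]:
    """Write a synthetic (tree, codings, truth) fixture."""
    out = Path(out_dir)
    _setup_logging(out)
    paths = synth.make_fixture(cfg, out)
    logger.info("simulate: wrote %s (seed=%d)", sorted(p.name for p in paths.values()), cfg.seed)
    return paths


def cmd_ltt(config: RunConfig) -> dict[str, Path]:
    """LTT tables for the tree (and configured clades) without a reconstruction."""
    out = Path(config.out)
    _setup_logging(out)
    chron = treedata.parse_chronogram(Path(config.tree).read_text())
    header = [f"config_hash={config.config_hash()}"]
    written = {"ltt": out / "ltt.tsv"}
    _write_atomic(written["ltt"], _frame_text(events_rates.ltt_curve(chron).to_frame(), header))
    for label, taxa in config.clades.items():
        curve = events_rates.ltt_curve(chron, mrca_of=taxa)
        written[f"ltt_{label}"] = out / f"ltt_{label}.tsv"
        _write_atomic(written[f"ltt_{label}"], _frame_text(curve.to_frame(), header))
    return written
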