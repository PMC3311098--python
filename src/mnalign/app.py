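"""Command-line interface: ``mnalign align | evaluate | simulate | fixture``.

A thin layer over the library.  ``align`` accepts repeated ``--tau`` to
sweep the seed threshold; preprocessing and clustering then run exactly
once and only the cheap alignment stages are re-executed per threshold,
which is how similarity/topology trade-off curves are produced.

Exit codes: 0 ok, 2 input error, 3 invariant violation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import click
import yaml

from . import engine, evaluation, io, synthetic
from .clustering import agglomerative_cluster, target_cluster_count
from .core import (
    Alignment,
    AlignmentParams,
    InputFormatError,
    InvariantViolation,
    NetworkCollection,
    SimilarityMatrix,
)
from .similarity import preprocess_similarity

logger = logging.getLogger("mnalign")


@dataclasses.dataclass
class RunConfig:
    """Validated inputs and parameters of one ``align`` invocation."""

    network_paths: dict[str, str]
    similarity_path: str
    annotation_path: str | None = None
    output_path: str = "out.aln"
    params: AlignmentParams = dataclasses.field(default_factory=AlignmentParams)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for p in [self.similarity_path, *self.network_paths.values()]:
            if not Path(p).exists():
                raise InputFormatError(f"input file not found: {p}")
        if self.annotation_path and not Path(self.annotation_path).exists():
            raise InputFormatError(
                f"annotation file not found: {self.annotation_path}"
            )


def align_sweep(
    nets: NetworkCollection,
    sim_raw: SimilarityMatrix,
    params: AlignmentParams,
    tau_list: list[float],
) -> tuple[list[tuple[float, Alignment, evaluation.MetricsReport]], engine.RunReport]:
    """Run the pipeline for several seed thresholds, preprocessing and
    clustering exactly once.

    Each entry of the result is bit-identical to a full pipeline run at the
    same tau.  The returned report counts clustering invocations (always 1).
    """
    if not tau_list:
        raise InputFormatError("align_sweep needs at least one tau")
    report = engine.RunReport(
        params=params,
        preprocess=params.preprocess,
        n_proteins=nets.n,
        n_networks=nets.k,
    )
    sim_dec = preprocess_similarity(nets, sim_raw) if params.preprocess else sim_raw
    m = params.cluster_count_override or target_cluster_count(nets, sim_dec)
    clusters = agglomerative_cluster(sim_dec, m, params.criterion)
    report.clustering_runs = 1
    report.n_clusters = len(clusters)

    results = []
    for tau in tau_list:
        seeds = engine.generate_seeds(clusters, nets, sim_dec, tau)
        tau_params = dataclasses.replace(params, tau=tau)
        state = engine.AlignmentState(nets, sim_dec)
        engine.expand_seeds(seeds, state, tau_params)
        engine.align_remaining(state, tau_params)
        aln = state.to_alignment()
        results.append((tau, aln, evaluation.compute_metrics(aln, nets, sim_raw)))
    return results, report


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def main(log_level: str) -> None:
    """Scalable global alignment of multiple PPI networks."""
    logging.basicConfig(level=log_level.upper(), stream=sys.stderr)


def _parse_nets(net_specs: tuple[str, ...]) -> dict[str, str]:
    paths: dict[str, str] = {}
    for spec in net_specs:
        if "=" not in spec:
            raise InputFormatError(
                f"--net expects NAME=edgelist.tsv, got {spec!r}"
            )
        name, path = spec.split("=", 1)
        paths[name] = path
    return paths


def _load_config(path: str | None) -> dict:
    if not path:
        return {}
    with open(path, "rt", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InputFormatError(f"config {path} must be a YAML mapping")
    return cfg


def _exit_on_error(fn):
    import functools

    @functools.wraps(fn)
    def wrapper(*args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except InputFormatError as exc:
            click.echo(f"input error: {exc}", err=True)
            sys.exit(2)
        except InvariantViolation as exc:
            click.echo(f"invariant violation: {exc}", err=True)
            sys.exit(3)

    return wrapper


@main.command()
@click.option("--net", "net_specs", multiple=True, help="NAME=edgelist.tsv")
@click.option("--sim", "sim_path", type=str, help="similarity TSV")
@click.option("--config", "config_path", type=str, default=None, help="YAML config")
@click.option("--preprocess/--no-preprocess", default=True, show_default=True)
@click.option("--tau", "taus", multiple=True, type=float, help="seed threshold (repeat to sweep)")
@click.option("--beta", type=float, default=0.1, show_default=True)
@click.option("--rho", type=float, default=0.5, show_default=True)
@click.option("--omega", type=float, default=2.5, show_default=True)
@click.option("--criterion", type=click.Choice(["i1", "i2"]), default="i1", show_default=True)
@click.option("--num-clusters", type=int, default=None, help="override n_sim/k")
@click.option("-o", "--output", default="out.aln", show_default=True)
@_exit_on_error
def align(
    net_specs, sim_path, config_path, preprocess, taus, beta, rho, omega,
    criterion, num_clusters, output,
) -> None:
    """Align networks; writes the alignment, an .unaligned sidecar and a
    JSON run report (a TSV trade-off table when sweeping several taus)."""
    cfg = _load_config(config_path)
    net_paths = _parse_nets(net_specs) or cfg.get("networks", {})
    sim_path = sim_path or cfg.get("similarity")
    if not net_paths or len(net_paths) < 2:
        raise InputFormatError("need at least two --net NAME=path inputs")
    if not sim_path:
        raise InputFormatError("--sim is required")
    param_cfg = cfg.get("params", {})
    params = AlignmentParams(
        tau=float(taus[0]) if taus else float(param_cfg.get("tau", 0.0)),
        beta=float(param_cfg.get("beta", beta)),
        rho=float(param_cfg.get("rho", rho)),
        omega=float(param_cfg.get("omega", omega)),
        criterion=param_cfg.get("criterion", criterion),
        cluster_count_override=num_clusters or param_cfg.get("num_clusters"),
        preprocess=preprocess,
    )
    config = RunConfig(net_paths, sim_path, output_path=output, params=params)
    nets = io.read_networks(config.network_paths)
    sim_raw = io.read_similarity_table(config.similarity_path, nets)

    tau_list = [float(t) for t in taus] or [params.tau]
    results, report = align_sweep(nets, sim_raw, params, tau_list)

    if len(results) == 1:
        _, aln, metrics = results[0]
        io.write_alignment(aln, output)
        io.write_unaligned(set(nets.vertices) - aln.covered(), output + ".unaligned")
        _write_report(report, metrics, output + ".report.json")
        click.echo(
            f"{len(aln)} match-sets, coverage {metrics.coverage}, "
            f"{metrics.conserved_edges} conserved edges, "
            f"average similarity {metrics.average_similarity:.6g}"
        )
    else:
        sweep_path = output + ".sweep.tsv"
        with open(sweep_path, "wt", encoding="utf-8") as fh:
            fh.write(
                "tau\tn_match_sets\tcoverage\tconserved_edges\t"
                "conserved_edge_rate\taverage_similarity\n"
            )
            for tau, aln, metrics in results:
                fh.write(
                    f"{tau:g}\t{metrics.n_match_sets}\t{metrics.coverage}\t"
                    f"{metrics.conserved_edges}\t{metrics.conserved_edge_rate:.6g}\t"
                    f"{metrics.average_similarity:.6g}\n"
                )
                io.write_alignment(aln, f"{output}.tau{tau:g}")
        click.echo(f"sweep of {len(results)} thresholds written to {sweep_path}")


def _write_report(report, metrics, path: str) -> None:
    payload = {
        "params": {
            k: v
            for k, v in dataclasses.asdict(report.params).items()
        },
        "preprocess": report.preprocess,
        "n_proteins": report.n_proteins,
        "n_networks": report.n_networks,
        "n_clusters": report.n_clusters,
        "n_seeds": report.n_seeds,
        "clustering_runs": report.clustering_runs,
        "merge_counters": dataclasses.asdict(report.counters),
        "metrics": metrics.as_dict() if metrics else None,
    }
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


@main.command()
@click.option("--aln", "aln_path", required=True)
@click.option("--net", "net_specs", multiple=True, required=True)
@click.option("--sim", "sim_path", required=True)
@click.option("--go", "go_path", default=None, help="annotation TSV")
@click.option("-o", "--output", default=None, help="JSON report path (default stdout)")
@_exit_on_error
def evaluate(aln_path, net_specs, sim_path, go_path, output) -> None:
    """Evaluate an existing alignment file."""
    nets = io.read_networks(_parse_nets(net_specs))
    sim_raw = io.read_similarity_table(sim_path, nets)
    aln = io.read_alignment(aln_path, nets)
    metrics = evaluation.compute_metrics(aln, nets, sim_raw)
    payload = metrics.as_dict()
    if go_path:
        ann = io.read_annotations(go_path)
        enr = evaluation.enrichment_report(aln, ann, nets)
        payload["enriched_terms"] = sorted(enr.enriched_terms)
        payload["n_enriched_terms"] = len(enr.enriched_terms)
        payload["match_set_min_pvalues"] = [p for p, _ in enr.per_set]
    text = json.dumps(payload, indent=2)
    if output:
        Path(output).write_text(text + "\n", encoding="utf-8")
    else:
        click.echo(text)


@main.command()
@click.option("--k", default=2, show_default=True)
@click.option("--n0", default=50, show_default=True)
@click.option("--p-edge", default=0.1, show_default=True)
@click.option("--p-del", default=0.1, show_default=True)
@click.option("--signal", default=100.0, show_default=True)
@click.option("--noise-rate", default=0.01, show_default=True)
@click.option("--noise-max", default=30.0, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("-o", "--outdir", required=True)
@_exit_on_error
def simulate(k, n0, p_edge, p_del, signal, noise_rate, noise_max, seed, outdir) -> None:
    """Write a planted-ortholog instance (edge lists, similarity, truth,
    annotations) into a directory."""
    nets, sim, truth = synthetic.generate_planted(
        k, n0, p_edge, p_del, signal, (noise_rate, noise_max), seed
    )
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_instance(nets, sim, out)
    with open(out / "truth.tsv", "wt", encoding="utf-8") as fh:
        for g in truth.groups:
            fh.write("\t".join(sorted(g)) + "\n")
    ann = synthetic.generate_annotations(truth, seed=seed)
    with open(out / "annotations.tsv", "wt", encoding="utf-8") as fh:
        for v in sorted(ann):
            for t in sorted(ann[v]):
                fh.write(f"{v}\t{t}\n")
    click.echo(f"instance with {nets.k} networks written to {out}")


@main.command()
@click.option("-o", "--outdir", required=True)
@_exit_on_error
def fixture(outdir) -> None:
    """Write the packaged two-network worked example to a directory."""
    nets, sim = synthetic.worked_example_fixture()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_instance(nets, sim, out)
    click.echo(f"fixture written to {out}")


def _write_instance(nets: NetworkCollection, sim: SimilarityMatrix, out: Path) -> None:
    for g in nets.networks:
        with open(out / f"{g.network_id}.edges.tsv", "wt", encoding="utf-8") as fh:
            for a, b in sorted(g.edges):
                fh.write(f"{a}\t{b}\n")
        with open(out / f"{g.network_id}.vertices.tsv", "wt", encoding="utf-8") as fh:
            for v in sorted(g.vertices):
                fh.write(v + "\n")
    with open(out / "similarity.tsv", "wt", encoding="utf-8") as fh:
        for a, b, s in sorted(sim.items()):
            fh.write(f"{a}\t{b}\t{s:g}\n")


if __name__ == "__main__":  # pragma: no cover
    main()
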