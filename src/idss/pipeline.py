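"""End-to-end run orchestration: counts in, atlas + graphs + report out."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import graphs as gr
from .bootstrap import bootstrap_bands
from .io import min_sample_check, read_coordinates, read_counts, write_frequencies
from .plotting import write_battleship
from .search import idss_search
from .spatial import spatial_test
from .types import SearchConfig, ValidationError, compute_frequencies

log = logging.getLogger("idss")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunReport:
    """Everything a run produced, JSON-round-trippable."""

    config: dict
    n_assemblages: int
    n_types: int
    row_totals: dict[str, int]
    low_sample_ids: list[str]
    empty_types: list[str]
    n_solutions: int
    n_valid_orders: int
    max_solution_size: int
    solutions: list[list[str]]
    output_files: dict[str, str]
    spatial: dict | None
    wall_clock_seconds: float
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        return cls(**d)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def run_pipeline(
    counts_path: str | Path,
    config: SearchConfig,
    coords_path: str | Path | None = None,
    out_dir: str | Path = "idss-out",
    *,
    metric: str = "euclidean",
    spatial_mode: str = "geo_edge_sum",
    spatial_resamples: int = 1000,
    min_n: int = 50,
    strict_n: bool = False,
    keep_all_ties: bool = False,
    max_battleships: int | None = None,
) -> RunReport:
    """Run the full analysis and write all artifacts under ``out_dir``.

    Outputs: ``frequencies.tsv``, ``bands.tsv``, ``atlas.json``,
    ``solutions.txt``, ``aggregate.graphml``/``.dot``,
    ``minmax.graphml``/``.dot``, per-solution battleship SVGs under
    ``battleship/``, ``spatial.json`` when coordinates are given, and
    ``report.json``. On any stage failure the partial outputs are removed
    and the raised error names the stage.
    """
    t0 = time.time()
    out_dir = Path(out_dir)
    created: list[Path] = []

    def track(path: Path) -> Path:
        created.append(path)
        return path

    stage = "read-input"
    try:
        counts = read_counts(counts_path)
        coords = read_coordinates(coords_path) if coords_path else None
        low = min_sample_check(counts, min_n)
        if low:
            log.warning("assemblages below n=%d: %s", min_n, ", ".join(low))
            if strict_n:
                raise ValidationError(
                    f"assemblages below minimum sample size {min_n}: {low}"
                )
        empty = counts.empty_type_columns()
        if empty:
            log.warning("type columns empty everywhere: %s", ", ".join(empty))
        out_dir.mkdir(parents=True, exist_ok=True)

        stage = "frequencies"
        freqs = compute_frequencies(counts)
        write_frequencies(freqs, track(out_dir / "frequencies.tsv"))

        stage = "bootstrap-bands"
        bands = bootstrap_bands(counts, config)
        bands.write_tsv(track(out_dir / "bands.tsv"))

        stage = "search"
        solutions = idss_search(counts, config, bands=bands)
        log.info(
            "search: %d maximal solutions (of %d valid orders), largest %d",
            len(solutions), solutions.n_valid_orders, solutions.max_size,
        )
        for k, n in sorted(solutions.frontier_sizes.items()):
            log.info("  frontier size %d: %d orders", k, n)
        solutions.write_json(track(out_dir / "atlas.json"))
        solutions.write_text(track(out_dir / "solutions.txt"))

        stage = "graphs"
        spatial_result = None
        graph_files: dict[str, str] = {}
        if len(solutions):
            agg = gr.aggregate(solutions, freqs, metric=metric)
            mm = gr.minmax(agg, keep_all_ties=keep_all_ties)
            for name, g in (("aggregate", agg), ("minmax", mm)):
                gml = track(out_dir / f"{name}.graphml")
                dot = track(out_dir / f"{name}.dot")
                gr.write_graphml(g, gml)
                gr.write_dot(g, dot, name=name)
                graph_files[f"{name}_graphml"] = str(gml)
                graph_files[f"{name}_dot"] = str(dot)

            stage = "battleships"
            bs_dir = out_dir / "battleship"
            bs_dir.mkdir(exist_ok=True)
            limit = len(solutions.orders)
            if max_battleships is not None:
                limit = min(limit, max_battleships)
            for i, order in enumerate(solutions.orders[:limit]):
                p = track(bs_dir / f"solution_{i + 1:04d}.svg")
                write_battleship(order, freqs, p, bands,
                                 title=f"solution {i + 1}")

            stage = "spatial-test"
            if coords is not None:
                spatial_result = spatial_test(
                    mm, coords, freqs,
                    mode=spatial_mode, resamples=spatial_resamples,
                    seed=config.seed, metric=metric,
                )
                spatial_result.write_json(track(out_dir / "spatial.json"))
                log.info(
                    "spatial test (%s): observed %.4f, p = %.4f",
                    spatial_mode, spatial_result.observed_statistic,
                    spatial_result.p_value,
                )

        stage = "report"
        report = RunReport(
            config=config.to_dict(),
            n_assemblages=counts.n_assemblages,
            n_types=counts.n_types,
            row_totals={
                a: int(t) for a, t in zip(counts.assemblage_ids, counts.row_totals)
            },
            low_sample_ids=low,
            empty_types=empty,
            n_solutions=len(solutions),
            n_valid_orders=solutions.n_valid_orders,
            max_solution_size=solutions.max_size,
            solutions=[list(o) for o in solutions.orders],
            output_files={
                "frequencies": str(out_dir / "frequencies.tsv"),
                "bands": str(out_dir / "bands.tsv"),
                "atlas": str(out_dir / "atlas.json"),
                "solutions": str(out_dir / "solutions.txt"),
                **graph_files,
            },
            spatial=(
                spatial_result.to_dict() if spatial_result is not None else None
            ),
            wall_clock_seconds=round(time.time() - t0, 3),
            seed=config.seed,
        )
        report.write_json(track(out_dir / "report.json"))
        return report
    except Exception as exc:
        for path in created:
            try:
                path.unlink(missing_ok=True)
            except OSError:
                pass
        raise PipelineError(stage, exc) from exc
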