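"""End-to-end pipeline: preprocess -> all-pairs causality -> association
network -> thresholding -> complex detection -> network statistics.

Every run writes its outputs plus a manifest (config and content hashes) to
the output directory; a failing stage aborts the run and removes partial
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import assoc, granger, io, modules, netstats, preprocess
from .exceptions import GranetError, ValidationError

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(GranetError, RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated parameters for a full pipeline run."""

    input: str
    out_dir: str
    diff: bool = True
    flat_filter_k: float | None = None
    top_n: int | None = None
    alpha: float = 0.05
    p_max: int | None = None
    lag: int | str = "auto"
    quantile: float = 0.975
    vwp: float = 0.2
    min_core: int = 2
    haircut: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.quantile < 1.0:
            raise ValidationError(f"quantile must be in (0, 1), got {self.quantile}")
        if not 0.0 <= self.vwp < 1.0:
            raise ValidationError(f"vwp must be in [0, 1), got {self.vwp}")
        if self.min_core < 0:
            raise ValidationError("min_core must be non-negative")
        if self.p_max is not None and self.p_max < 1:
            raise ValidationError("p_max must be >= 1")
        if self.lag != "auto" and (not isinstance(self.lag, int) or self.lag < 1):
            raise ValidationError("lag must be 'auto' or a positive integer")
        if self.flat_filter_k is not None and self.flat_filter_k < 0:
            raise ValidationError("flat_filter_k must be non-negative")
        if self.top_n is not None and self.top_n < 1:
            raise ValidationError("top_n must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write outputs plus a manifest to ``cfg.out_dir``.

    Returns a dict with the in-memory results (``network``, ``complexes``,
    ``stats``) and the paths written.  Any stage failure removes the partial
    outputs and re-raises with the stage name.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "read input"
    try:
        matrix = io.read_expression(cfg.input)
        logger.info("read %d genes x %d time points", matrix.n_genes, matrix.n_times)

        stage = "preprocess"
        removed: list[str] = []
        if cfg.flat_filter_k is not None:
            matrix, removed = preprocess.filter_flat(matrix, cfg.flat_filter_k)
            logger.info("flat filter removed %d gene(s)", len(removed))
        if cfg.top_n is not None:
            matrix = preprocess.rank_by_spectral_power(matrix, cfg.top_n)
        if cfg.diff:
            matrix = preprocess.first_difference(matrix)

        stage = "pairwise causality"
        directed = granger.pairwise_causality(
            matrix, alpha=cfg.alpha, p_max=cfg.p_max, lag=cfg.lag
        )
        logger.info("performed %d directed tests", directed.n_tests)

        stage = "association network"
        network = assoc.symmetrize_max(directed)
        thresholded = assoc.threshold_quantile(network, cfg.quantile)

        stage = "complex detection"
        graph = thresholded.to_graph(include_isolated=False)
        complexes = modules.find_complexes(
            graph, vwp=cfg.vwp, haircut=cfg.haircut, min_core=cfg.min_core
        )
        logger.info("found %d complex(es)", len(complexes))

        stage = "network statistics"
        stats = netstats.summary(thresholded.to_graph(include_isolated=True))

        stage = "write outputs"
        paths = {
            "directed": out_dir / "directed.tsv",
            "network_full": out_dir / "network_full.tsv",
            "network": out_dir / "network.tsv",
            "network_graphml": out_dir / "network.graphml",
            "complexes": out_dir / "complexes.tsv",
            "stats": out_dir / "stats.json",
        }
        io.write_directed(directed, paths["directed"])
        written.append(paths["directed"])
        io.write_network(network, paths["network_full"], fmt="edgelist")
        written.append(paths["network_full"])
        io.write_network(thresholded, paths["network"], fmt="edgelist")
        written.append(paths["network"])
        io.write_network(thresholded, paths["network_graphml"])
        written.append(paths["network_graphml"])
        io.write_complexes(complexes, paths["complexes"])
        written.append(paths["complexes"])
        with open(paths["stats"], "w") as fh:
            json.dump(stats.to_dict(), fh, indent=2, sort_keys=True)
        written.append(paths["stats"])

        manifest = {
            "config": cfg.to_dict(),
            "n_genes_tested": matrix.n_genes,
            "n_directed_tests": directed.n_tests,
            "removed_flat_genes": removed,
            "threshold_cutoff": thresholded.threshold.cutoff,
            "outputs": {name: _sha256(p) for name, p in paths.items()},
        }
        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    return {
        "network": thresholded,
        "complexes": complexes,
        "stats": stats,
        "manifest": manifest,
        "paths": {name: str(p) for name, p in paths.items()} | {"manifest": str(manifest_path)},
    }
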