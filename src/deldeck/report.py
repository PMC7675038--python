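"""Fingerprint visualization and the end-to-end pipeline shell.

Selection fingerprints are displayed either as the classic tridimensional
plot (CodeA index, CodeB index, sequence counts) or the more compact
pseudo-2D scatter in which dot colour encodes counts on a jet scale.  Plots
are advisory artifacts: every quantitative statement in the pipeline summary
comes from the tabular outputs, never from pixels.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import yaml

from . import decode as _decode
from . import design as _design
from . import enrich as _enrich
from . import simulate as _simulate
from .decode import CountMatrix

logger = logging.getLogger("deldeck")


def setup_logging(log_file: Optional[str | Path] = None, level: int = logging.INFO) -> None:
    """Route package logs to stderr and optionally a file."""
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


def manifest_hash(manifest_dir: str | Path) -> str:
    """SHA-256 over the manifest files, so outputs are traceable to a design."""
    h = hashlib.sha256()
    for p in sorted(Path(manifest_dir).iterdir()):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Fingerprint plots
# ---------------------------------------------------------------------------

def fingerprint_plot(
    matrix: CountMatrix,
    path: str | Path,
    representation: str = "pseudo2d",
    title: str = "",
    cmap: str = "jet",
) -> Path:
    """Render a selection fingerprint to an image file.

    ``representation="3d"``: CodeA/CodeB indices on x,y and sequence counts
    on z.  ``representation="pseudo2d"``: CodeA vs CodeB scatter of non-zero
    cells, colour-mapped counts.  Deterministic for fixed input and settings.
    """
    if matrix.counts.size == 0:
        raise ValueError("cannot plot an empty matrix")
    path = Path(path)
    ai, bi = np.nonzero(matrix.counts)
    c = matrix.counts[ai, bi]
    fig = plt.figure(figsize=(7, 5))
    if representation == "3d":
        ax = fig.add_subplot(projection="3d")
        if ai.size:
            ax.stem(ai, bi, c, basefmt=" ", markerfmt=".")
        ax.set_zlabel("sequence counts")
    elif representation == "pseudo2d":
        ax = fig.add_subplot()
        if ai.size:
            sc = ax.scatter(ai, bi, c=c, s=8, cmap=cmap)
            fig.colorbar(sc, ax=ax, label="sequence counts")
        ax.set_xlim(-1, len(matrix.a_ids))
        ax.set_ylim(-1, len(matrix.b_ids))
    else:
        raise ValueError(f"unknown representation {representation!r}")
    ax.set_xlabel("CodeA index")
    ax.set_ylabel("CodeB index")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class RunConfig:
    """Configuration for one end-to-end run (design -> simulate -> decode -> enrich)."""

    manifest_dir: str
    out_dir: str
    scenario: str = "sp_selection"
    seed: int = 0
    reads: Optional[str] = None  # pre-existing FASTQ; skips simulation
    max_mismatch: int = 1
    baseline: str = "uniform"
    ef_min: float = _enrich.DEFAULT_EF_MIN
    count_min: int = _enrich.DEFAULT_COUNT_MIN
    representation: str = "pseudo2d"
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: RunConfig) -> dict:
    """Execute design-validate -> (simulate) -> decode -> enrich -> report.

    Returns the summary dict (also written as summary.json).  Re-running
    with an identical config writes byte-identical tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out / "run.log")

    try:
        manifest = _design.load_manifest(config.manifest_dir)
        mhash = manifest_hash(config.manifest_dir)
        logger.info("design ok: %d members, manifest sha256=%s", manifest.n_members, mhash)
    except Exception as e:
        raise PipelineError("design", str(e)) from e

    fastq = config.reads
    try:
        if fastq is None:
            scenario = _simulate.scenario_presets(config.scenario, manifest, seed=config.seed)
            captured = _simulate.simulate_capture(
                scenario.truth, scenario.sp_mode, manifest, seed=config.seed
            )
            fastq = out / "reads.fastq"
            _simulate.sequence_reads(
                captured, manifest, scenario.cfg, fastq, truth_path=out / "truth.tsv"
            )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("simulate", str(e)) from e

    try:
        matrix = _decode.decode_fastq(fastq, manifest, max_mismatch=config.max_mismatch)
        matrix.to_tsv(out / "counts.tsv")
    except Exception as e:
        raise PipelineError("decode", str(e)) from e

    try:
        table = _enrich.enrichment_factors(matrix, baseline=config.baseline)
        table.to_tsv(out / "ef.tsv")
        hits = _enrich.call_hits(table, ef_min=config.ef_min, count_min=config.count_min)
        hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    except Exception as e:
        raise PipelineError("enrich", str(e)) from e

    try:
        if config.make_plots:
            fingerprint_plot(
                matrix, out / f"fingerprint_{config.representation}.png",
                representation=config.representation,
            )
        summary = _decode.summarize(matrix)
        summary["manifest_sha256"] = mhash
        summary["seed"] = config.seed
        summary["top_hits"] = hits.head(10).to_dict(orient="records")
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    except Exception as e:
        raise PipelineError("report", str(e)) from e
    return summary
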