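"""Config-driven workflow: depth -> TAD -> marker depth -> abundance -> cutoff -> ANIr.

A run is described by one declarative mapping (usually loaded from YAML):

.. code-block:: yaml

    genomes:
      - {id: pop1, fasta: refs/pop1.fasta}
    samples:
      - id: day1
        alignments: {pop1: aln/day1_pop1.tsv}
        marker_hits: aln/day1_rpoB.tsv
    marker_reference_lengths: [4000]
    params:
      central_fraction: 0.8
      bin_width: 0.5
      drop_orders: 3.0
      floor: 95.0
      detection_threshold: 1.0e-4
      anir_weighting: aligned_bases

Every run writes a ``combined.tsv`` (one row per genome x sample), per-pair
BedGraph depth files, and a ``manifest.json`` recording version, config,
input checksums and timestamps. The pipeline holds no hidden state: its
output equals the composition of the individual subcommands.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from . import abundance as ab
from . import recruitment as rec
from .io_formats import read_fasta, read_tabular_alignments, write_bedgraph

__all__ = ["PipelineError", "RunManifest", "run_pipeline", "DEFAULT_PARAMS"]

DEFAULT_PARAMS: dict[str, Any] = {
    "central_fraction": 0.8,
    "bin_width": 0.5,
    "drop_orders": 3.0,
    "floor": 95.0,
    "detection_threshold": 1e-4,
    "anir_weighting": "aligned_bases",
    "marker_min_bitscore": 0.0,
    "marker_min_pident": 0.0,
    "cutoff_override": None,  # fix the ANIr cutoff instead of detecting it
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted once per run."""

    tool: str = "magpop"
    version: str = __version__
    seed: int | None = None
    config: dict = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def run_pipeline(config: dict, outdir: str | Path) -> Path:
    """Execute the per-(genome, sample) workflow described by ``config``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    manifest = RunManifest(seed=config.get("seed"), config=config, started=_now())

    def _load(path_str: str, stage: str, what: str):
        path = Path(path_str)
        if not path.exists():
            raise PipelineError(f"stage {stage}: missing {what} file {path}")
        manifest.input_checksums[str(path)] = _sha256(path)
        return path

    genomes: dict[str, list] = {}
    for g in config.get("genomes", []):
        path = _load(g["fasta"], "load-genomes", f"genome {g['id']}")
        try:
            genomes[g["id"]] = read_fasta(path)
        except Exception as exc:
            raise PipelineError(f"stage load-genomes: genome {g['id']}: {exc}") from exc

    ref_lengths = config.get("marker_reference_lengths")
    if not ref_lengths:
        raise PipelineError("stage config: marker_reference_lengths missing or empty")

    rows = []
    for sample in config.get("samples", []):
        sid = sample["id"]
        try:
            hits = read_tabular_alignments(_load(sample["marker_hits"], "marker-depth", f"marker hits of sample {sid}"))
            hits = ab.simple_marker_filter(
                hits, params["marker_min_bitscore"], params["marker_min_pident"]
            )
            marker = ab.marker_depth(hits, ref_lengths, sample_id=sid)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage marker-depth: sample {sid}: {exc}") from exc

        for gid, aln_path in sample.get("alignments", {}).items():
            if gid not in genomes:
                raise PipelineError(f"stage depth: sample {sid} references unknown genome {gid}")
            try:
                alignments = read_tabular_alignments(
                    _load(aln_path, "depth", f"alignments of {gid} in {sid}")
                )
                profile = rec.compute_depth(alignments, genomes[gid], genome_id=gid)
                bg = outdir / f"depth_{sid}_{gid}.bedgraph"
                write_bedgraph(profile.to_bedgraph_tracks(), bg)
                manifest.outputs.append(str(bg))
                tad80 = rec.tad(profile, central_fraction=params["central_fraction"])
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage depth/tad: sample {sid} genome {gid}: {exc}") from exc

            try:
                frac = ab.relative_abundance(tad80, marker)
                detected = ab.detect(frac, params["detection_threshold"])
            except Exception as exc:
                raise PipelineError(f"stage abundance: sample {sid} genome {gid}: {exc}") from exc

            try:
                glen = sum(len(r) for r in genomes[gid])
                hist = rec.identity_histogram(alignments, glen, bin_width=params["bin_width"])
                if params["cutoff_override"] is not None:
                    cutoff_val = float(params["cutoff_override"])
                    found = True
                elif hist.total_bases > 0:
                    cut = rec.detect_cutoff(
                        hist, drop_orders=params["drop_orders"], floor=params["floor"]
                    )
                    cutoff_val, found = cut.cutoff, cut.discontinuity_found
                else:
                    cutoff_val, found = params["floor"], False
                try:
                    anir_val = rec.anir(alignments, cutoff_val, params["anir_weighting"])
                except rec.NoRecruitedReads:
                    anir_val = math.nan
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage cutoff/anir: sample {sid} genome {gid}: {exc}") from exc

            rows.append(
                {
                    "sample": sid,
                    "genome": gid,
                    "tad": tad80,
                    "marker_depth": marker.depth,
                    "abundance": frac,
                    "detected": detected,
                    "cutoff": cutoff_val,
                    "discontinuity_found": found,
                    "anir": anir_val,
                }
            )

    combined = outdir / "combined.tsv"
    pd.DataFrame(rows).to_csv(combined, sep="\t", index=False, float_format="%.6g")
    manifest.outputs.append(str(combined))
    manifest.finished = _now()
    manifest.write(outdir / "manifest.json")
    return outdir
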