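"""Loaders for the packaged reference fixtures.

The fixtures transcribe the published summary tables of a rice
low-temperature-germinability study: 24 substitution-line detections with
their segment definitions (plus four overlapping non-significant lines), a
40-gene region table with per-gene qualifying-variant counts and seed
expression categories, five recombinant progeny populations, and the F2
genotype class counts.  Marker cM positions are fixture values tuned to the
public SSR map so that the interval algebra reproduces the published
integrated intervals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io as sio
from .candidate_genes import GeneRecord
from .f2_genetics import RecombinantPopulation
from .sssl_core import DetectionResult, GeneticMap, SubstitutedSegment

F2_CLASS_COUNTS = (85, 173, 98)  # recipient hom., het., donor hom.
F2_EXPECTED_RATIO = (0.25, 0.5, 0.25)
F2_CLASS_MEANS = (0.52, 0.65, 0.78)  # germination proportion by genotype class

NONSIGNIFICANT_LINES = ("S25", "S26", "S27", "S28")


def _data_path(name: str):
    return resources.files("segmap.data").joinpath(name)


def load_genetic_map() -> GeneticMap:
    with resources.as_file(_data_path("genetic_map.tsv")) as p:
        return sio.read_genetic_map(p)


def load_segments(gmap: GeneticMap | None = None) -> dict[str, SubstitutedSegment]:
    gmap = gmap or load_genetic_map()
    with resources.as_file(_data_path("segments.tsv")) as p:
        return sio.read_segments(p, gmap)


def load_detections() -> list[DetectionResult]:
    """The 24 line-level QTL detections (season-averaged summaries)."""
    with resources.as_file(_data_path("detections.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"chromosome": str})
    out = []
    for r in df.itertuples():
        sign = 1 if r.a_mean > 0 else -1
        out.append(
            DetectionResult(
                line_id=r.line_id,
                detected_seasons=frozenset(r.detected_seasons),
                detected=True,
                a_mean=float(r.a_mean),
                a_sd=float(r.a_sd),
                r2_mean=float(r.r2_mean) / 100.0,
                r2_sd=float(r.r2_sd) / 100.0,
                sign=sign,
                donor_id=r.donor,
            )
        )
    return out


def load_nonsignificant(gmap: GeneticMap | None = None):
    """(line_id, segment) pairs for the overlapping non-detected lines."""
    segments = load_segments(gmap)
    return [(lid, segments[lid]) for lid in NONSIGNIFICANT_LINES]


def load_detection_segments(gmap: GeneticMap | None = None):
    segments = load_segments(gmap)
    return {
        lid: seg for lid, seg in segments.items() if lid not in NONSIGNIFICANT_LINES
    }


def load_gene_table(with_assay: bool = True) -> list[GeneRecord]:
    with resources.as_file(_data_path("gene_table.tsv")) as gp:
        if with_assay:
            with resources.as_file(_data_path("assay_expression.tsv")) as ap:
                return sio.read_gene_table(gp, ap)
        return sio.read_gene_table(gp)


def load_recombinants() -> list[RecombinantPopulation]:
    with resources.as_file(_data_path("recombinants.tsv")) as p:
        return sio.read_recombinants(p)
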