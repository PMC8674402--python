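"""Readers and writers for the flat-file formats the pipeline consumes.

All formats are plain text: phenotype CSV, map/segment/F2/variant TSV, BED
intervals, and JSON reports.  VCF input (per-sample allele depths for the
two parents and two bulks) is parsed with a minimal text reader so that
uncompressed VCFs work without index files.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import pandas as pd

from .bsa_index import DeltaTrack, PooledVariantSite
from .candidate_genes import GeneRecord
from .errors import InputError
from .f2_genetics import F2Individual, RecombinantPopulation
from .intervals import Interval
from .sssl_core import GeneticMap, SubstitutedSegment
from .substitution_mapping import IntegratedQTL

END_TOKEN = "end"


def read_genetic_map(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"marker", "chromosome", "cM"}
    if not required.issubset(df.columns):
        raise InputError(f"map file needs columns {sorted(required)}")
    df = df.sort_values(["chromosome", "cM"], kind="stable")
    return GeneticMap(
        [(r.marker, str(r.chromosome), float(r.cM)) for r in df.itertuples()]
    )


def _resolve(gmap: GeneticMap, chrom: str, marker: str, side: str) -> float:
    if marker.strip().lower() == END_TOKEN:
        lo, hi = gmap.extent(chrom)
        return lo if side == "start" else hi
    mchrom, pos = gmap.position(marker)
    if mchrom != chrom:
        raise InputError(f"marker {marker} is on chromosome {mchrom}, not {chrom}")
    return pos


def read_segments(
    path: str | Path, gmap: GeneticMap
) -> dict[str, SubstitutedSegment]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, SubstitutedSegment] = {}
    for r in df.itertuples():
        chrom = str(r.chromosome)
        core = Interval(
            _resolve(gmap, chrom, r.core_start_marker, "start"),
            _resolve(gmap, chrom, r.core_end_marker, "end"),
        )
        maximal = Interval(
            _resolve(gmap, chrom, r.max_start_marker, "start"),
            _resolve(gmap, chrom, r.max_end_marker, "end"),
        )
        out[r.line_id] = SubstitutedSegment(chrom, core, maximal)
    return out


def read_phenotypes(path: str | Path) -> dict[str, dict[str, list[float]]]:
    """Phenotype CSV -> {line_id: {season: [replicate proportions]}}.

    Accepts either a precomputed ``proportion`` column or ``germinated`` and
    ``sown`` count columns.
    """
    df = pd.read_csv(path)
    if "proportion" in df.columns:
        props = df["proportion"].astype(float)
    elif {"germinated", "sown"}.issubset(df.columns):
        props = df["germinated"].astype(float) / df["sown"].astype(float)
    else:
        raise InputError("need 'proportion' or 'germinated'+'sown' columns")
    out: dict[str, dict[str, list[float]]] = {}
    for (line_id, season), grp in props.groupby(
        [df["line_id"].astype(str), df["season"].astype(str)]
    ):
        out.setdefault(line_id, {})[season] = list(grp)
    return out


def read_f2(path: str | Path) -> tuple[list[F2Individual], list[str]]:
    """F2 TSV with individual_id, marker columns coded {1,2,3}/NA, phenotype."""
    df = pd.read_csv(path, sep="\t")
    markers = [c for c in df.columns if c not in {"individual_id", "phenotype"}]
    individuals = []
    for r in df.itertuples(index=False):
        row = r._asdict()
        genotypes = {
            m: (None if pd.isna(row[m]) else int(row[m])) for m in markers
        }
        pheno = None if pd.isna(row["phenotype"]) else float(row["phenotype"])
        individuals.append(
            F2Individual(str(row["individual_id"]), genotypes, pheno)
        )
    return individuals, markers


def read_recombinants(path: str | Path) -> list[RecombinantPopulation]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    pops = []
    for r in df.itertuples():
        pops.append(
            RecombinantPopulation(
                recomb_id=str(r.recomb_id),
                chromosome=str(r.chromosome),
                het_interval=Interval(float(r.het_start_bp), float(r.het_end_bp)),
                marker_id=str(r.marker_id),
                marker_pos=float(r.marker_pos_bp) if "marker_pos_bp" in df.columns else None,
                r=float(r.r) if "r" in df.columns else None,
                p=float(r.p) if "p" in df.columns else None,
            )
        )
    return pops


def read_variant_tsv(path: str | Path) -> list[PooledVariantSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        PooledVariantSite(
            chromosome=str(r.chrom),
            position=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            ref_hi=int(r.ref_hi),
            alt_hi=int(r.alt_hi),
            ref_lo=int(r.ref_lo),
            alt_lo=int(r.alt_lo),
            variant_class=str(getattr(r, "variant_class", "SNP")),
        )
        for r in df.itertuples()
    ]


def read_variant_vcf(
    path: str | Path,
    tolerant_sample: str,
    sensitive_sample: str,
    donor_sample: str | None = None,
    recipient_sample: str | None = None,
) -> list[PooledVariantSite]:
    """Parse an uncompressed VCF with per-sample AD fields into pooled sites.

    When both parent samples are given, sites where the parents are not
    opposite homozygotes are dropped and depths are oriented so that 'alt'
    means the donor allele.
    """
    samples: list[str] = []
    sites: list[PooledVariantSite] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            chrom, pos, _, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            if "," in alt:
                continue  # multi-allelic sites are skipped
            fmt = fields[8].split(":")
            if "AD" not in fmt:
                raise InputError("VCF records lack an AD FORMAT field")
            ad_i = fmt.index("AD")
            gt_i = fmt.index("GT") if "GT" in fmt else None
            per_sample = dict(zip(samples, fields[9:]))

            def ad(sample: str) -> tuple[int, int]:
                parts = per_sample[sample].split(":")[ad_i].split(",")
                return int(parts[0]), int(parts[1])

            def gt(sample: str) -> str:
                return per_sample[sample].split(":")[gt_i] if gt_i is not None else "./."

            donor_is_alt = True
            if donor_sample and recipient_sample:
                gd = gt(donor_sample).replace("|", "/")
                gr = gt(recipient_sample).replace("|", "/")
                if {gd, gr} == {"0/0", "1/1"}:
                    donor_is_alt = gd == "1/1"
                else:
                    continue  # parents not opposite homozygotes
            rt, at = ad(tolerant_sample)
            rs, as_ = ad(sensitive_sample)
            if not donor_is_alt:
                rt, at, rs, as_ = at, rt, as_, rs
            variant_class = "InDel" if len(ref) != len(alt) else "SNP"
            sites.append(
                PooledVariantSite(
                    chromosome=chrom,
                    position=pos,
                    ref=ref,
                    alt=alt,
                    ref_hi=rt,
                    alt_hi=at,
                    ref_lo=rs,
                    alt_lo=as_,
                    variant_class=variant_class,
                )
            )
    return sites


def read_gene_table(
    path: str | Path, assay_path: str | Path | None = None
) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t")
    assay: dict[str, str] = {}
    if assay_path is not None:
        adf = pd.read_csv(assay_path, sep="\t")
        assay = dict(zip(adf["gene_id"], adf["expr_assay"]))
    return [
        GeneRecord(
            gene_id=str(r.gene_id),
            annotation=str(r.annotation),
            indels=int(r.indels),
            snps=int(r.snps),
            expr_db=str(r.expr_db),
            expr_assay=assay.get(str(r.gene_id)),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# writers


def write_detections_tsv(path: str | Path, detections, segments=None) -> None:
    rows = []
    for d in detections:
        rows.append(
            {
                "line_id": d.line_id,
                "donor": d.donor_id,
                "detected": d.detected,
                "detected_seasons": "".join(sorted(d.detected_seasons)),
                "a_mean": d.a_mean,
                "a_sd": d.a_sd,
                "r2_mean": d.r2_mean,
                "r2_sd": d.r2_sd,
                "sign": d.sign,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_qtl_tsv(path: str | Path, qtls: list[IntegratedQTL]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["QTL", "donors", "chromosome", "interval_cM", "length_cM", "a", "a_sd", "r2_pct", "r2_sd_pct", "members"]
        )
        for q in qtls:
            ivs = ";".join(f"{iv.start:g}-{iv.end:g}" for iv in q.intervals)
            w.writerow(
                [
                    q.name,
                    ",".join(q.donors),
                    q.chromosome,
                    ivs,
                    f"{q.total_length:g}",
                    f"{q.a_mean:.2f}",
                    f"{q.a_sd:.2f}",
                    f"{q.r2_mean * 100:.1f}" if abs(q.r2_mean) <= 1 else f"{q.r2_mean:.1f}",
                    f"{q.r2_sd * 100:.1f}" if abs(q.r2_mean) <= 1 else f"{q.r2_sd:.1f}",
                    ",".join(q.member_ids),
                ]
            )


def write_track_tsv(path: str | Path, track: DeltaTrack) -> None:
    cols = {
        "chrom": [track.chromosome] * len(track.centers),
        "center_bp": track.centers,
        "delta": track.values,
        "n_sites": track.n_sites,
    }
    for level, (lo, hi) in track.bands.items():
        cols[f"lower_{level:g}"] = lo
        cols[f"upper_{level:g}"] = hi
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_bed(path: str | Path, intervals, chromosome=None) -> None:
    """BED (0-based half-open) from candidate or physical intervals."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom = getattr(iv, "chromosome", chromosome)
            start = int(getattr(iv, "start"))
            end = int(getattr(iv, "end"))
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
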