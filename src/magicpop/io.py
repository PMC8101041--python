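"""Text-format input/output for panels, mosaics, traits and truth records.

Founder panels round-trip through a GT-only VCF (inbred haploid calls coded
as homozygous diploid genotypes) plus a delimited site map carrying the
genetic positions; gene windows go to BED (0-based half-open); ancestry
mosaics to a BED-like block table; trait tables to tab-delimited text with a
``line_id`` first column; truth records to JSON.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .synthpop import FounderPanel

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_sitemap",
    "read_sitemap",
    "write_windows_bed",
    "read_windows_bed",
    "write_traits",
    "read_traits",
    "write_mosaics",
    "read_mosaics",
    "write_panel",
    "read_panel",
    "write_truth_json",
]


def write_vcf(panel: FounderPanel, path) -> None:
    """GT-only VCF; founder haploid calls written as 0/0 or 1/1."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.founder_ids)
            + "\n"
        )
        chroms = panel.sites["chrom"].to_numpy()
        pos = panel.sites["pos_bp"].to_numpy()
        for j in range(panel.n_sites):
            calls = "\t".join(
                "1/1" if panel.genotypes[f, j] else "0/0"
                for f in range(panel.n_founders)
            )
            fh.write(f"{chroms[j]}\t{pos[j]}\tsite{j + 1}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path):
    """Read a GT-only VCF into (sample_ids, sites DataFrame, genotype matrix).

    Genotypes are allele counts divided by ploidy, so homozygous-coded inbred
    calls come back as 0/1. Only the fixed columns and GT field are parsed.
    """
    samples, chroms, pos, rows = None, [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chroms.append(parts[0])
            pos.append(int(parts[1]))
            gts = []
            for call in parts[9:]:
                alleles = call.split(":")[0].replace("|", "/").split("/")
                vals = [int(a) for a in alleles if a != "."]
                gts.append(int(round(sum(vals) / len(vals))) if vals else -1)
            rows.append(gts)
    sites = pd.DataFrame({"chrom": chroms, "pos_bp": pos})
    return samples, sites, np.array(rows, dtype=np.int8).T


def write_sitemap(panel: FounderPanel, path) -> None:
    panel.sites.to_csv(path, sep="\t", index=False)


def read_sitemap(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_windows_bed(windows: pd.DataFrame, path) -> None:
    """Gene/promoter windows as BED (0-based half-open)."""
    bed = pd.DataFrame(
        {
            "chrom": windows["chrom"],
            "start": windows["start_bp"] - 1,
            "end": windows["end_bp"],
            "name": windows["gene_id"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_windows_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name"])
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "start_bp": bed["start"] + 1,
            "end_bp": bed["end"],
        }
    )


def write_traits(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_mosaics(mosaics, path, bp_per_morgan: float | None = None) -> None:
    """Mosaics as a delimited block table (line, chrom, copy, start, end, founder).

    Positions are Morgans unless ``bp_per_morgan`` is given, in which case
    they are also reported in bp.
    """
    rows = []
    for m in mosaics:
        for chrom, pair in m.chroms.items():
            for ci, copy in enumerate(pair):
                for s, e, f in copy:
                    row = {"line_id": m.line_id, "chrom": chrom, "copy": ci,
                           "start_m": s, "end_m": e, "founder": f}
                    if bp_per_morgan:
                        row["start_bp"] = int(s * bp_per_morgan)
                        row["end_bp"] = int(e * bp_per_morgan)
                    rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_mosaics(path):
    from .magicsim import MosaicGenome

    tab = pd.read_csv(path, sep="\t")
    out = []
    for line_id, sub in tab.groupby("line_id", sort=False):
        chroms = {}
        for chrom, csub in sub.groupby("chrom", sort=False):
            pair = []
            for ci in (0, 1):
                blocks = csub[csub["copy"] == ci].sort_values("start_m")
                pair.append(
                    [
                        (float(r.start_m), float(r.end_m), int(r.founder))
                        for r in blocks.itertuples()
                    ]
                )
            chroms[chrom] = tuple(pair)
        out.append(MosaicGenome(line_id=line_id, chroms=chroms))
    return out


def write_panel(panel: FounderPanel, prefix) -> None:
    """Panel as VCF + site map + windows BED + block-truth JSON."""
    write_vcf(panel, f"{prefix}.vcf")
    write_sitemap(panel, f"{prefix}.sitemap.tsv")
    write_windows_bed(panel.windows, f"{prefix}.windows.bed")
    if panel.block_truth is not None:
        truth = panel.block_truth.copy()
        truth["groups"] = truth["groups"].apply(lambda g: [int(x) for x in g])
        write_truth_json(truth.to_dict(orient="records"), f"{prefix}.blocks.json")


def read_panel(prefix) -> FounderPanel:
    samples, sites, geno = read_vcf(f"{prefix}.vcf")
    sitemap = read_sitemap(f"{prefix}.sitemap.tsv")
    windows = read_windows_bed(f"{prefix}.windows.bed")
    panel = FounderPanel(
        founder_ids=samples,
        sites=sitemap,
        genotypes=geno.astype(np.uint8),
        windows=windows,
    )
    panel.validate()
    return panel


def write_truth_json(records, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(records, fh, default=_default, indent=1)
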