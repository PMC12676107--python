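"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as minimal GT-only VCF (read back through cyvcf2) or
as a 0/1 CSV; plot tables, curves and fluorescence traces as CSV;
synthetic ground truth as a JSON sidecar; gene annotations as GFF3
(parsed with gffutils); trees as Newick with bootstrap support.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .popgen import MISSING, GenotypeMatrix

__all__ = [
    "write_vcf", "read_vcf", "write_genotype_csv", "read_genotype_csv",
    "write_aci_csv", "read_aci_csv", "write_trace_csv", "read_trace_csv",
    "write_truth_json", "read_gff3_genes", "write_newick",
]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Minimal GT-only VCF; homozygous 0/0 vs 1/1, ./. for missing."""
    gt_map = {0: "0/0", 1: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=photoadapt\n")
        for c in sorted(set(gm.chrom), key=str):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.accessions) + "\n")
        for j in range(gm.n_snps):
            gts = "\t".join(gt_map[int(v)] for v in gm.codes[:, j])
            fh.write(f"{gm.chrom[j]}\t{gm.pos[j]}\t{gm.snp_ids[j]}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF into a 0/1(/missing) matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    codes_cols, snp_ids, chrom, pos = [], [], [], []
    for var in vcf:
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types)
        col = np.full(len(gt), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 3] = 1
        codes_cols.append(col)
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
    vcf.close()
    return GenotypeMatrix(
        codes=np.column_stack(codes_cols) if codes_cols else
        np.empty((len(accessions), 0), dtype=np.int8),
        accessions=accessions, snp_ids=snp_ids,
        chrom=np.array(chrom), pos=np.array(pos, dtype=np.int64),
    )


def write_genotype_csv(gm: GenotypeMatrix, path) -> None:
    """0/1 CSV, accessions as rows; missing written as empty cells.
    Two leading metadata rows carry the chromosome and position map."""
    df = pd.DataFrame(gm.as_float(), index=gm.accessions, columns=gm.snp_ids)
    header = pd.DataFrame([gm.chrom, gm.pos], index=["#chrom", "#pos"],
                          columns=gm.snp_ids)
    pd.concat([header, df]).to_csv(path, index_label="accession")


def read_genotype_csv(path) -> GenotypeMatrix:
    raw = pd.read_csv(path, index_col="accession")
    chrom = raw.loc["#chrom"].to_numpy()
    pos = raw.loc["#pos"].astype(np.int64).to_numpy()
    body = raw.drop(index=["#chrom", "#pos"]).astype(float)
    codes = body.to_numpy()
    out = np.full(codes.shape, MISSING, dtype=np.int8)
    out[codes == 0.0] = 0
    out[codes == 1.0] = 1
    return GenotypeMatrix(codes=out, accessions=list(body.index),
                          snp_ids=list(body.columns), chrom=chrom, pos=pos)


# ---------------------------------------------------------------------------
# curves and traces
# ---------------------------------------------------------------------------

def write_aci_csv(curve, path, qin: float = 1800.0) -> None:
    """Instrument-style per-curve CSV: obs, CO2_r, Ci, A, gsw, Qin, Tleaf."""
    n = len(curve.ci)
    pd.DataFrame({
        "obs": np.arange(1, n + 1),
        "CO2_r": curve.ca_ref if curve.ca_ref is not None else np.full(n, np.nan),
        "Ci": curve.ci,
        "A": curve.a_net,
        "gsw": np.full(n, curve.gs_op if curve.gs_op is not None else np.nan),
        "Qin": np.full(n, qin),
        "Tleaf": np.full(n, curve.tleaf),
    }).to_csv(path, index=False)


def read_aci_csv(path):
    from .photofit import AciCurve

    df = pd.read_csv(path)
    gs = df["gsw"].dropna()
    return AciCurve(
        ci=df["Ci"].to_numpy(float), a_net=df["A"].to_numpy(float),
        ca_ref=df["CO2_r"].to_numpy(float) if "CO2_r" in df else None,
        gs_op=float(gs.iloc[0]) if len(gs) else None,
        tleaf=float(df["Tleaf"].iloc[0]) if "Tleaf" in df else 25.0,
    )


def write_trace_csv(trace, path) -> None:
    """Trace CSV with Fm/F0 header lines then time_s, Fs, FmPrime rows."""
    with open(path, "w") as fh:
        fh.write(f"# Fm={trace.fm_dark}\n# F0={trace.f0_dark}\n")
        pd.DataFrame({"time_s": trace.time, "Fs": trace.fs,
                      "FmPrime": trace.fm_prime}).to_csv(fh, index=False)


def read_trace_csv(path, actinic_off: float = 600.0, end: float = 1400.0):
    from .npqkinetics import FluorTrace

    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, ln in enumerate(lines):
        if ln.startswith("#"):
            key, val = ln[1:].strip().split("=")
            meta[key.strip()] = float(val)
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    return FluorTrace(time=df["time_s"].to_numpy(float),
                      fs=df["Fs"].to_numpy(float),
                      fm_prime=df["FmPrime"].to_numpy(float),
                      fm_dark=meta["Fm"], f0_dark=meta["F0"],
                      actinic_off=actinic_off, end=end)


# ---------------------------------------------------------------------------
# truth / annotation / trees
# ---------------------------------------------------------------------------

def write_truth_json(truth, path) -> None:
    payload = {
        "true_q": truth.true_q.tolist(),
        "true_subpop": truth.true_subpop.to_dict(),
        "causal_snps": [list(c) for c in truth.causal_snps],
        "true_genotype_values": truth.true_genotype_values.to_dict(),
        "true_curve_params": {
            acc: {kind: dataclasses.asdict(params)
                  for kind, params in kinds.items()}
            for acc, kinds in truth.true_curve_params.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 file: gene_id, chrom, start, end."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = [{"gene_id": g.id, "chrom": g.seqid, "start": g.start, "end": g.end}
            for g in db.features_of_type("gene")]
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def write_newick(tree, path) -> None:
    tree.write(str(path), format="newick")
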