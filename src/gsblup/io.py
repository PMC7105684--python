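"""Reading and writing genotype, phenotype and kinship files.

Supported genotype dialects: VCF v4.x (GT with optional DP/AD, via cyvcf2),
HapMap-style diploid tables (tab-separated, IUPAC single-letter or two-letter
AA/AB coding), and a generic CSV table of genets x markers coded {0, 1, 2}
with empty/NA for missing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .markers import HET, HOM_ALT, HOM_REF, MISSING, GenotypeCallSet

logger = logging.getLogger(__name__)

_IUPAC_HET = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}

#: HapMap metadata columns preceding the sample columns.
HAPMAP_META_COLS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeCallSet:
    """Read genotype calls from ``path`` in the named dialect.

    Depth matrices are populated when the source provides them (VCF DP/AD);
    otherwise ``depth`` is ``None`` and depth-based filters must be skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "hapmap":
        return _read_hapmap(path)
    if format in ("tabular", "csv"):
        return _read_dosage_csv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeCallSet:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    genet_ids = list(vcf.samples)
    if len(set(genet_ids)) != len(genet_ids):
        raise ValidationError("duplicate genet ID in VCF sample header")

    marker_ids, alleles, call_rows, dp_rows, rd_rows, ad_rows = [], [], [], [], [], []
    any_depth = False
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        marker_ids.append(vid)
        alleles.append((var.REF, ",".join(var.ALT) if var.ALT else "."))
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types)
        row = np.full(gt.shape, MISSING, dtype=np.int8)
        row[gt == 0] = HOM_REF
        row[gt == 1] = HET
        row[gt == 3] = HOM_ALT
        call_rows.append(row)
        try:
            dp = var.format("DP")
        except KeyError:  # tag absent from the header
            dp = None
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if dp is not None:
            any_depth = True
            dp_rows.append(np.maximum(dp.reshape(-1).astype(float), 0))
        else:
            dp_rows.append(None)
        if ad is not None and ad.shape[1] >= 2:
            any_depth = True
            adf = ad.astype(float)
            adf[adf < 0] = 0  # cyvcf2 encodes missing AD as negative
            rd_rows.append(adf[:, 0])
            ad_rows.append(adf[:, 1])
        else:
            rd_rows.append(None)
            ad_rows.append(None)

    n, m = len(genet_ids), len(marker_ids)
    calls = np.stack(call_rows, axis=1) if m else np.zeros((n, 0), np.int8)

    def _stack(rows, fallback_rows=None):
        if not any(r is not None for r in rows):
            return None
        out = np.zeros((n, m))
        for j, r in enumerate(rows):
            if r is not None:
                out[:, j] = r
        return out

    depth = _stack(dp_rows) if any_depth else None
    ref_depth = _stack(rd_rows)
    alt_depth = _stack(ad_rows)
    if depth is None and ref_depth is not None:
        depth = ref_depth + alt_depth
    return GenotypeCallSet(
        genet_ids=genet_ids,
        marker_ids=marker_ids,
        alleles=alleles,
        calls=calls,
        depth=depth,
        ref_depth=ref_depth,
        alt_depth=alt_depth,
    )


def _read_hapmap(path: Path) -> GenotypeCallSet:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot parse HapMap table {path}: {exc}") from exc
    n_meta = sum(1 for c in df.columns if c.lower() in
                 [c2.lower() for c2 in HAPMAP_META_COLS])
    if n_meta < 4 or "alleles" not in [c.lower() for c in df.columns]:
        raise ParseError(f"{path} does not look like a HapMap table")
    cols_lower = {c.lower(): c for c in df.columns}
    meta_cols = [cols_lower[c.lower()] for c in HAPMAP_META_COLS
                 if c.lower() in cols_lower]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if len(set(sample_cols)) != len(sample_cols):
        raise ValidationError("duplicate genet ID in HapMap header")

    marker_ids = df[cols_lower["rs#"]].tolist()
    allele_str = df[cols_lower["alleles"]].tolist()
    alleles = []
    for i, a in enumerate(allele_str):
        parts = str(a).split("/")
        if len(parts) < 2:
            raise ParseError(
                f"line {i + 2}: malformed alleles field {a!r}"
            )
        alleles.append((parts[0], ",".join(parts[1:])))

    calls = np.full((len(sample_cols), len(marker_ids)), MISSING, dtype=np.int8)
    for j, (ref, alt) in enumerate(alleles):
        alt0 = alt.split(",")[0]
        col = df[sample_cols].iloc[j].astype(str).str.upper().values
        for i, code in enumerate(col):
            calls[i, j] = _decode_hapmap(code, ref.upper(), alt0.upper(), j)
    return GenotypeCallSet(
        genet_ids=list(sample_cols),
        marker_ids=marker_ids,
        alleles=alleles,
        calls=calls,
        depth=None,
    )


def _decode_hapmap(code: str, ref: str, alt: str, j: int) -> int:
    if code in ("N", "NN", "NA", "", "NAN", "./.", "-", "--"):
        return MISSING
    if len(code) == 1:
        pair = _IUPAC_HET.get(code, code * 2)
    elif len(code) == 2:
        pair = code
    else:
        raise ParseError(f"marker column {j}: bad genotype code {code!r}")
    s = "".join(sorted(pair))
    if s == "".join(sorted(ref + ref)):
        return HOM_REF
    if s == "".join(sorted(alt + alt)):
        return HOM_ALT
    if s == "".join(sorted(ref + alt)):
        return HET
    return MISSING


def _read_dosage_csv(path: Path) -> GenotypeCallSet:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise ParseError(f"cannot parse genotype CSV {path}: {exc}") from exc
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"duplicate genet IDs: {dupes}")
    vals = df.to_numpy(dtype=float)
    calls = np.full(vals.shape, MISSING, dtype=np.int8)
    ok = ~np.isnan(vals)
    if not np.isin(vals[ok], [0, 1, 2]).all():
        raise ParseError(f"{path}: dosage entries must be 0/1/2 or NA")
    calls[ok] = vals[ok].astype(np.int8)
    return GenotypeCallSet(
        genet_ids=[str(g) for g in df.index],
        marker_ids=[str(c) for c in df.columns],
        alleles=[("A", "B")] * df.shape[1],
        calls=calls,
        depth=None,
    )


#: Required columns of the phenotype table.
PHENO_COLUMNS = ["genet_id", "cycle", "site", "year", "row", "col", "trait", "value"]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype CSV with the standard plot-record schema.

    Required columns: genet_id, cycle, site, year, row, col, trait, value
    (``program`` optional).  Missing values may be empty cells; rows with a
    missing trait value are dropped.
    """
    df = pd.read_csv(path)
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"phenotype file {path} lacks columns {missing}")
    df = df.dropna(subset=["value"]).copy()
    df["genet_id"] = df["genet_id"].astype(str)
    for c in ("year", "row", "col"):
        df[c] = df[c].astype(int)
    return df


def write_kinship(k, path: str | Path) -> None:
    """Serialize a KinshipMatrix to HDF5 (``.h5``) or CSV, losslessly."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=k.values)
            f.create_dataset(
                "genet_ids", data=np.array(k.genet_ids, dtype="S")
            )
            f.attrs["theta"] = k.theta
            f.attrs["bend_applied"] = k.bend_applied
            f.attrs["bend_magnitude"] = k.bend_magnitude
    else:
        pd.DataFrame(k.values, index=k.genet_ids, columns=k.genet_ids).to_csv(path)


def read_kinship(path: str | Path):
    from .kinship import KinshipMatrix

    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            return KinshipMatrix(
                genet_ids=[g.decode() for g in f["genet_ids"][:]],
                values=f["values"][:],
                theta=float(f.attrs["theta"]),
                bend_applied=bool(f.attrs["bend_applied"]),
                bend_magnitude=float(f.attrs["bend_magnitude"]),
            )
    df = pd.read_csv(path, index_col=0)
    return KinshipMatrix(
        genet_ids=[str(g) for g in df.index],
        values=df.to_numpy(float),
        theta=float("nan"),
        bend_applied=False,
        bend_magnitude=0.0,
    )


def write_vcf(calls: GenotypeCallSet, path: str | Path) -> None:
    """Write a call set as a minimal VCF v4.2 text file (GT:DP[:AD])."""
    path = Path(path)
    has_ad = calls.has_allele_depth
    has_dp = calls.has_depth
    fmt = "GT" + (":DP" if has_dp else "") + (":AD" if has_ad else "")
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as f:
        f.write("##fileformat=VCFv4.2\n")
        f.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            f.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if has_ad:
            f.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths">\n'
            )
        f.write("##contig=<ID=1>\n")
        f.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(calls.genet_ids) + "\n"
        )
        for j, mid in enumerate(calls.marker_ids):
            ref, alt = calls.alleles[j]
            fields = ["1", str(j + 1), mid, ref, alt, ".", "PASS", ".", fmt]
            for i in range(calls.n_genets):
                s = gt_str[int(calls.calls[i, j])]
                if has_dp:
                    s += f":{int(calls.depth[i, j])}"
                if has_ad:
                    s += f":{int(calls.ref_depth[i, j])},{int(calls.alt_depth[i, j])}"
                fields.append(s)
            f.write("\t".join(fields) + "\n")
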