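"""File I/O for the pipeline's tabular formats.

Methylation matrices travel as TSV with CpGs as rows, a leading
``# scale=beta|M`` comment line carrying the scale tag, sample ids in the
header, and ``NA`` for masked entries.  Round trips are lossless
including the mask.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .qc import MethylationMatrix

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_genotypes",
    "read_genotypes",
    "write_json",
    "read_yaml",
]


def write_matrix(mm: MethylationMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# scale={mm.scale}\n")
        fh.write("cpg_id\t" + "\t".join(mm.sample_ids) + "\n")
        for i, cpg in enumerate(mm.cpg_ids):
            row = [
                "NA" if mm.mask[i, j] else repr(float(mm.values[i, j]))
                for j in range(mm.n_samples)
            ]
            fh.write(cpg + "\t" + "\t".join(row) + "\n")


def read_matrix(path: str | Path, scale: str | None = None) -> MethylationMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("# scale="):
            tag = first.split("=", 1)[1]
            header = fh.readline()
        else:
            tag = scale or "beta"
            header = first
        sample_ids = header.rstrip("\n").split("\t")[1:]
        cpg_ids, rows = [], []
        for lineno, line in enumerate(fh, start=3):
            parts = line.rstrip("\n").split("\t")
            cpg_ids.append(parts[0])
            vals = []
            for col, cell in enumerate(parts[1:]):
                if cell == "NA":
                    vals.append(np.nan)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {cell!r} at row {parts[0]!r}, "
                        f"column {sample_ids[col]!r}"
                    ) from None
            rows.append(vals)
    values = np.asarray(rows, dtype=float)
    if scale is not None:
        tag = scale
    if tag == "beta":
        bad = np.argwhere((values < 0) | (values > 1))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"beta value {values[i, j]} out of [0, 1] at row "
                f"{cpg_ids[i]!r}, column {sample_ids[j]!r}"
            )
    return MethylationMatrix(values, cpg_ids, sample_ids, scale=tag)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    if "sample_id" not in sheet.columns:
        raise ValueError("sample sheet must have a sample_id column")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    return sheet


def write_genotypes(genotypes: pd.DataFrame, path: str | Path) -> None:
    # stored SNPs x samples on disk
    genotypes.T.to_csv(path, sep="\t", index_label="snp_id", na_rep="NA")


def read_genotypes(path: str | Path) -> pd.DataFrame:
    g = pd.read_csv(path, sep="\t", index_col="snp_id", na_values="NA")
    return g.T  # back to samples x SNPs


def write_detection_p(
    det: np.ndarray, cpg_ids: list[str], sample_ids: list[str], path: str | Path
) -> None:
    df = pd.DataFrame(det, index=pd.Index(cpg_ids, name="cpg_id"), columns=sample_ids)
    df.to_csv(path, sep="\t")


def read_detection_p(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cpg_id")


def write_cohort(cohort, out_dir: str | Path) -> None:
    """Write a simulated cohort's files (sample sheet, matrices, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_sample_sheet(cohort.sample_sheet, out / "sample_sheet.csv")
    write_matrix(cohort.beta, out / "beta.tsv")
    write_detection_p(
        cohort.detection_p, cohort.beta.cpg_ids, cohort.beta.sample_ids,
        out / "detection_p.tsv",
    )
    write_genotypes(cohort.genotypes, out / "genotypes.tsv")
    write_json(cohort.ground_truth.to_dict(), out / "ground_truth.json")
    cohort.reference_profiles.to_csv(out / "reference_profiles.tsv", sep="\t")


def load_cohort(in_dir: str | Path):
    """Read back a cohort directory written by :func:`write_cohort`."""
    from .simulate import Cohort, GroundTruth

    d = Path(in_dir)
    sheet = read_sample_sheet(d / "sample_sheet.csv")
    beta = read_matrix(d / "beta.tsv")
    det = read_detection_p(d / "detection_p.tsv")
    if list(det.index) != beta.cpg_ids or list(det.columns) != beta.sample_ids:
        raise ValueError("detection-p ids do not match the beta matrix")
    genotypes = read_genotypes(d / "genotypes.tsv")
    if list(genotypes.index) != beta.sample_ids or list(
        sheet["sample_id"]
    ) != beta.sample_ids:
        raise ValueError("sample ids differ across cohort files")
    with open(d / "ground_truth.json") as fh:
        gt = GroundTruth.from_dict(json.load(fh))
    ref = pd.read_csv(d / "reference_profiles.tsv", sep="\t", index_col=0)
    return Cohort(sheet, beta, det.values, genotypes, gt, ref)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def hits_to_bed(hits: pd.DataFrame, annotation: pd.DataFrame, path: str | Path) -> int:
    """Export hit CpGs as BED (0-based, half-open) for genome-browser use.

    ``annotation`` carries 1-based positions (array-manifest convention)
    in columns cpg_id/chrom/pos; the BED interval for a CpG at 1-based
    position p is [p-1, p).  Returns the number of rows written.
    """
    ann = annotation.set_index("cpg_id") if "cpg_id" in annotation.columns else annotation
    missing = [c for c in hits["cpg_id"] if c not in ann.index]
    if missing:
        raise KeyError(f"no annotation for hit CpG {missing[0]!r}")
    n = 0
    with open(path, "w") as fh:
        for cpg in hits["cpg_id"]:
            chrom = ann.loc[cpg, "chrom"]
            pos = int(ann.loc[cpg, "pos"])
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{cpg}\n")
            n += 1
    return n


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
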