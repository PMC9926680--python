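"""Read-depth CNV calling against a panel-of-normals baseline.

The baseline is a small set of CNV-negative samples (the clinical
strategy uses five).  Per-exon mean depths are normalized per sample by
its median autosomal depth, the test sample's normalized depth is
divided by the mean of the applicable baseline columns, and the ratio is
thresholded.  Because the baseline contains both sexes and the test
sample's sex is always specified, sex-chromosome regions are compared
only against same-sex baseline columns — a normal male X then sits at
ratio 1.0, so deletions and duplications remain callable on X and Y.

Thresholds (het deletion <= 0.7, hom deletion <= 0.1, duplication
>= 1.3) are conventional ratio cut-offs, exposed in ``CnvThresholds``.
No segmentation (HMM/CBS) and no GC correction: consecutive same-state
regions of a gene are simply merged into one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Consequence, Genotype, Sex, VariantCall

REGION_COLUMNS = ["gene", "exon", "chrom", "start", "end"]


@dataclass
class CnvThresholds:
    del_het: float = 0.7
    del_hom: float = 0.1
    dup: float = 1.3


@dataclass
class CnvCall:
    gene: str
    chrom: str
    start: int
    end: int
    state: str  # del_het | del_hom | dup
    ratio: float


def read_depth_matrix(path) -> pd.DataFrame:
    """Depth matrix TSV: region columns (gene, exon, chrom, start, end)
    then one column of mean depths per sample."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"depth matrix lacks region columns: {missing}")
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_depth_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _sample_columns(m: pd.DataFrame) -> list:
    return [c for c in m.columns if c not in REGION_COLUMNS]


def normalize_depths(m: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample column by its own median autosomal depth, so
    autosomal medians equal 1 and columns are scale-free."""
    out = m.copy()
    autosomal = ~m["chrom"].astype(str).isin(["X", "Y", "chrX", "chrY"])
    if not autosomal.any():
        raise ValueError("depth matrix contains no autosomal regions to normalize by")
    for col in _sample_columns(m):
        if (m[col] < 0).any():
            raise ValueError(f"negative depth in sample {col}")
        med = float(m.loc[autosomal, col].median())
        if med <= 0:
            raise ValueError(f"sample {col} has zero median autosomal depth")
        out[col] = m[col] / med
    return out


def call_cnv(
    sample: str,
    normalized: pd.DataFrame,
    baseline_samples: list,
    baseline_sexes: dict,
    sample_sex: Sex,
    thresholds: CnvThresholds = CnvThresholds(),
) -> list:
    """Call CNVs for one normalized sample column against the normalized
    baseline columns.  Sex-chromosome rows use only same-sex baseline
    columns; at least two applicable baseline samples are required.
    """
    for col in [sample] + list(baseline_samples):
        if col not in normalized.columns:
            raise ValueError(f"sample column {col!r} absent from matrix")
    sex_rows = normalized["chrom"].astype(str).isin(["X", "Y", "chrX", "chrY"])
    same_sex = [s for s in baseline_samples if baseline_sexes.get(s) == sample_sex]
    if sex_rows.any() and len(same_sex) < 2:
        raise ValueError(
            f"need >=2 baseline samples of sex {sample_sex.value} for "
            f"sex-chromosome calls, have {len(same_sex)}"
        )
    if len(baseline_samples) < 2:
        raise ValueError("need >=2 baseline samples")

    ref = np.empty(len(normalized))
    ref[~sex_rows.values] = normalized.loc[~sex_rows, baseline_samples].mean(axis=1)
    if sex_rows.any():
        ref[sex_rows.values] = normalized.loc[sex_rows, same_sex].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = normalized[sample].to_numpy() / ref

    def state_of(r: float):
        if not np.isfinite(r):
            return None
        if r <= thresholds.del_hom:
            return "del_hom"
        if r <= thresholds.del_het:
            return "del_het"
        if r >= thresholds.dup:
            return "dup"
        return None

    calls: list[CnvCall] = []
    current = None
    rows = normalized[REGION_COLUMNS].to_dict("records")
    for i, row in enumerate(rows):
        st = state_of(ratio[i])
        if (
            current is not None
            and st == current["state"]
            and row["gene"] == current["gene"]
            and row["chrom"] == current["chrom"]
        ):
            current["end"] = row["end"]
            current["ratios"].append(ratio[i])
            continue
        if current is not None:
            calls.append(_flush(current))
        current = None
        if st is not None:
            current = {
                "gene": row["gene"],
                "chrom": row["chrom"],
                "start": row["start"],
                "end": row["end"],
                "state": st,
                "ratios": [ratio[i]],
            }
    if current is not None:
        calls.append(_flush(current))
    return calls


def _flush(c: dict) -> CnvCall:
    return CnvCall(
        gene=c["gene"],
        chrom=c["chrom"],
        start=int(c["start"]),
        end=int(c["end"]),
        state=c["state"],
        ratio=float(np.mean(c["ratios"])),
    )


def cnv_calls_to_variants(calls: list, patient_id: str) -> list:
    """Convert CnvCalls to VariantCall records (consequence cnv_del /
    cnv_dup) so depth-based events flow through panel restriction,
    classification, and reporting like any other variant."""
    out = []
    for c in calls:
        out.append(
            VariantCall(
                patient_id=patient_id,
                chrom=c.chrom,
                pos=c.start,
                ref="N",
                alt="<DEL>" if c.state.startswith("del") else "<DUP>",
                gene=c.gene,
                consequence=(
                    Consequence.cnv_del if c.state.startswith("del") else Consequence.cnv_dup
                ),
                genotype=Genotype.hom_alt if c.state == "del_hom" else Genotype.het,
            )
        )
    return out
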