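"""RNA-seq post-processing: expression filter, DEG thresholds, concordance.

This module consumes the outputs of a standard differential-expression
workflow — a raw count matrix with per-gene multi-mapping percentages and
per-contrast tables of (gene, logFC, FDR) — and implements the downstream
set logic: the low-expression/multi-mapping gene filter, FDR and logFC
thresholding into up-/down-regulated sets, and the comparison of two
contrasts into a Venn-style concordance partition (dataset-specific up and
down, common concordant up and down, and discordantly regulated genes).
Fitting the DE model itself (e.g. edgeR's GLMs) is upstream and out of
scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

PERC_MM_COLUMN = "perc_MM"


def _count_columns(counts: pd.DataFrame) -> list[str]:
    return [c for c in counts.columns if c != PERC_MM_COLUMN]


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: count · 10⁶ / library size, per sample column.

    ``counts`` is genes × samples; a ``perc_MM`` column, if present, is
    ignored here and preserved by callers.  Every library size (column sum)
    must be positive.
    """
    cols = _count_columns(counts)
    mat = counts[cols]
    if (mat.values < 0).any():
        raise ValueError("counts must be non-negative")
    lib = mat.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {', '.join(zero.index)}")
    return mat * 1e6 / lib


def filter_genes(
    counts: pd.DataFrame,
    cpm_threshold: float = 1.0,
    n_min: int | None = None,
    perc_mm_threshold: float = 20.0,
    require_both: bool = True,
) -> tuple[pd.DataFrame, pd.Index]:
    """Remove low-expression, high-multi-mapping genes.

    A gene is removed when it is expressed (cpm ≥ ``cpm_threshold``) in
    fewer than ``n_min`` samples AND its multi-mapping-read percentage
    exceeds ``perc_mm_threshold``.  ``require_both=False`` switches to the
    OR reading (either condition alone removes the gene).

    ``n_min`` has no universal default — it depends on the design; pass the
    smallest group size.  Returns (kept matrix, removed gene index).
    """
    if n_min is None:
        raise ValueError(
            "n_min must be supplied (suggested: the smallest group size)"
        )
    n_samples = len(_count_columns(counts))
    if not (1 <= n_min <= n_samples):
        raise ValueError(f"n_min must be in [1, {n_samples}]")
    if PERC_MM_COLUMN not in counts.columns:
        raise ValueError(f"counts must carry a {PERC_MM_COLUMN!r} column")

    expressed_in = (cpm(counts) >= cpm_threshold).sum(axis=1)
    low_expression = expressed_in < n_min
    high_mm = counts[PERC_MM_COLUMN] > perc_mm_threshold
    removed = (low_expression & high_mm) if require_both else (low_expression | high_mm)
    return counts.loc[~removed], counts.index[removed]


def _normalize_ids(genes: pd.Series) -> pd.Series:
    return genes.astype(str).str.strip().str.upper()


@dataclass
class DEGSets:
    """Up- and down-regulated gene-id sets from one thresholded contrast."""

    up: set[str]
    down: set[str]
    flagged_zero_logfc: set[str]

    @property
    def all(self) -> set[str]:
        return self.up | self.down


def threshold_degs(
    table: pd.DataFrame,
    fdr_cut: float = 0.05,
    logfc_cut: float | None = None,
) -> DEGSets:
    """Split a (gene, logFC, FDR) table into up- and down-regulated sets.

    up: FDR < fdr_cut and logFC > 0 (> +logfc_cut when given);
    down: FDR < fdr_cut and logFC < 0 (< −logfc_cut when given).
    Significant genes with logFC exactly 0 fit neither direction; they are
    flagged and assigned to neither set.
    """
    for col in ("gene", "logFC", "FDR"):
        if col not in table.columns:
            raise ValueError(f"DEG table lacks column {col!r}")
    ids = _normalize_ids(table["gene"])
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique()
        raise ValueError(f"duplicate gene ids in DEG table: {dups[:5]}")
    fdr = table["FDR"].to_numpy(float)
    if ((fdr < 0) | (fdr > 1)).any():
        raise ValueError("FDR values must lie in [0, 1]")
    lfc = table["logFC"].to_numpy(float)
    sig = fdr < fdr_cut
    up_cut = logfc_cut if logfc_cut is not None else 0.0
    up = sig & (lfc > up_cut)
    down = sig & (lfc < -up_cut)
    zero = sig & (lfc == 0.0)
    return DEGSets(
        up=set(ids[up]),
        down=set(ids[down]),
        flagged_zero_logfc=set(ids[zero]),
    )


@dataclass
class VennPartition:
    """Disjoint concordance categories from comparing two DEG contrasts.

    ``discordant`` holds genes significant in both contrasts with opposite
    logFC signs.  Derived totals follow the usual Venn reading: the common
    compartment is concordant-up + concordant-down + discordant.
    """

    a_up: set[str]
    a_down: set[str]
    b_up: set[str]
    b_down: set[str]
    common_up: set[str]
    common_down: set[str]
    discordant: set[str]

    @property
    def total_a_specific(self) -> int:
        return len(self.a_up) + len(self.a_down)

    @property
    def total_b_specific(self) -> int:
        return len(self.b_up) + len(self.b_down)

    @property
    def total_common(self) -> int:
        return len(self.common_up) + len(self.common_down) + len(self.discordant)

    def categories(self) -> dict[str, set[str]]:
        return {
            "a_up": self.a_up, "a_down": self.a_down,
            "b_up": self.b_up, "b_down": self.b_down,
            "common_up": self.common_up, "common_down": self.common_down,
            "discordant": self.discordant,
        }

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.categories().items()}

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.categories().values():
            out |= s
        return out


def compare_datasets(a: DEGSets, b: DEGSets) -> VennPartition:
    """Partition two thresholded DEG contrasts by concordance of direction."""
    for name, s in (("A", a), ("B", b)):
        if s.up & s.down:
            raise ValueError(f"dataset {name}: genes appear both up and down")
    in_b = b.all
    in_a = a.all
    return VennPartition(
        a_up=a.up - in_b,
        a_down=a.down - in_b,
        b_up=b.up - in_a,
        b_down=b.down - in_a,
        common_up=a.up & b.up,
        common_down=a.down & b.down,
        discordant=(a.up & b.down) | (a.down & b.up),
    )


def export_gene_lists(partition: VennPartition, out_dir: str | Path) -> Path:
    """One sorted gene-list file per category plus a summary JSON."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, genes in partition.categories().items():
        (out_dir / f"{name}.txt").write_text(
            "\n".join(sorted(genes)) + ("\n" if genes else "")
        )
    summary = {
        **partition.sizes(),
        "total_a_specific": partition.total_a_specific,
        "total_b_specific": partition.total_b_specific,
        "total_common": partition.total_common,
        "union_size": len(partition.union),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return out_dir


def read_gene_lists(out_dir: str | Path) -> dict[str, set[str]]:
    """Round-trip reader for :func:`export_gene_lists` output."""
    out_dir = Path(out_dir)
    out: dict[str, set[str]] = {}
    for path in sorted(out_dir.glob("*.txt")):
        text = path.read_text().strip()
        out[path.stem] = set(text.split("\n")) if text else set()
    return out


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV DEG table with columns (gene, logFC, FDR)."""
    return pd.read_csv(path, sep="\t")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV count matrix (genes × samples) with a perc_MM column."""
    return pd.read_csv(path, sep="\t", index_col=0)
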