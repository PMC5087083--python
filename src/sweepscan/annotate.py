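"""Candidate-region annotation: gene intersection and over-representation.

Gene models come in as GFF3 (1-based closed, converted on import) or BED
(already 0-based half-open). A gene is assigned to a region iff the two
intervals overlap by at least 1 bp — no flank by default, configurable.
Over-representation of user-supplied gene sets (GMT) is a one-sided
hypergeometric tail with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

GENE_COLUMNS = ["chrom", "start", "end", "strand", "gene_id", "gene_name"]


class AnnotationError(RuntimeError):
    pass


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.rstrip(";").split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_annotation(path: str | Path, feature_type: str = "gene") -> pd.DataFrame:
    """Load gene models from GFF3 or BED into 0-based half-open coordinates.

    GFF3 rows of ``feature_type`` are kept; start converts 1-based closed ->
    0-based half-open. Duplicate gene_ids collapse to their union span (one
    row, earliest start to latest end) with a warning via the returned frame's
    attrs['n_collapsed']. Malformed lines are fatal with their line number.
    """
    path = Path(path)
    is_gff = path.suffix.lower() in {".gff", ".gff3"} or ".gff" in path.name.lower()
    rows = []
    for i, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        try:
            if is_gff:
                if len(f) < 9:
                    raise ValueError("fewer than 9 GFF3 columns")
                if f[2] != feature_type:
                    continue
                start, end = int(f[3]) - 1, int(f[4])
                attrs = _parse_gff3_attributes(f[8])
                gene_id = attrs.get("ID") or attrs.get("gene_id")
                if gene_id is None:
                    raise ValueError("no ID/gene_id attribute")
                name = attrs.get("Name") or attrs.get("gene_name") or gene_id
                strand = f[6]
            else:
                if len(f) < 3:
                    raise ValueError("fewer than 3 BED columns")
                start, end = int(f[1]), int(f[2])
                gene_id = f[3] if len(f) > 3 else f"{f[0]}:{start}-{end}"
                name = gene_id
                strand = f[5] if len(f) > 5 else "."
            if end <= start:
                raise ValueError(f"empty interval [{start}, {end})")
            rows.append((f[0], start, end, strand, gene_id, name))
        except (ValueError, IndexError) as exc:
            raise AnnotationError(f"{path}:{i}: malformed line ({exc})") from exc

    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    n_dup = int(genes["gene_id"].duplicated().sum())
    if n_dup:
        genes = (
            genes.groupby("gene_id", as_index=False, sort=False)
            .agg(
                chrom=("chrom", "first"),
                start=("start", "min"),
                end=("end", "max"),
                strand=("strand", "first"),
                gene_name=("gene_name", "first"),
            )[GENE_COLUMNS]
        )
    genes = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    genes.attrs["n_collapsed"] = n_dup
    return genes


def regions_to_genes(
    regions: pd.DataFrame, genes: pd.DataFrame, flank: int = 0
) -> tuple[pd.DataFrame, list[str]]:
    """Assign genes to candidate regions by >= 1 bp interval overlap.

    ``flank`` extends each region symmetrically before intersecting (0 by
    default). Returns (per-region table with a comma-joined ``genes`` column,
    sorted deduplicated union gene-id list).
    """
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.gene_id)

    per_region = regions.copy().reset_index(drop=True)
    hits_col: list[str] = []
    union: set[str] = set()
    for row in per_region.itertuples():
        tree = trees.get(row.chrom)
        start = max(0, int(row.start) - flank)
        end = int(row.end) + flank
        ids = sorted({iv.data for iv in tree.overlap(start, end)}) if tree else []
        union.update(ids)
        hits_col.append(",".join(ids))
    per_region["genes"] = hits_col
    return per_region, sorted(union)


@dataclass
class GeneSetMap:
    """GMT-style mapping: term id -> (description, member gene ids)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetMap":
        sets = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise AnnotationError(f"{path}:{i}: GMT line needs term, desc, >=1 gene")
            sets[f[0]] = (f[1], frozenset(g for g in f[2:] if g))
        return cls(sets)


def enrich(
    genes: set[str], background: set[str], genesets: GeneSetMap
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term, BH-adjusted.

    P(X >= k) for k = |genes ∩ term| drawn |genes| times without replacement
    from |background| with |term ∩ background| successes. Terms with no
    background overlap are skipped (counted in attrs['n_skipped']).
    """
    if not genes <= background:
        raise ValueError("selected genes must be a subset of the background")
    M, n_draw = len(background), len(genes)
    rows, skipped = [], 0
    for term, (desc, members) in genesets.sets.items():
        K = len(members & background)
        if K == 0:
            skipped += 1
            continue
        k = len(members & genes)
        p = float(hypergeom.sf(k - 1, M, K, n_draw))
        rows.append((term, desc, K, k, p))
    out = pd.DataFrame(rows, columns=["term", "description", "n_background", "n_overlap", "p"])
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = pd.Series(dtype=float)
    out.attrs["n_skipped"] = skipped
    return out.sort_values("p", kind="stable").reset_index(drop=True)
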