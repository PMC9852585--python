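"""Collation of genome-wide-significant signals into quasi-independent loci.

Signals below the adjusted threshold are pooled across traits, sorted by
position, and chain-linked: consecutive signals at most 1 Mb apart belong to
the same locus (single-linkage, so a locus can span more than 1 Mb end to
end).  Loci are screened against a known-association catalogue and against
reference BMI/WHR-style association tables, and annotated with genes within
a flank of the lead variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Locus", "collate_significant", "cluster_loci", "filter_known",
           "annotate_genes", "read_catalogue", "read_gene_table"]


@dataclass
class Locus:
    chrom: str
    start: int                  # min member position
    end: int                    # max member position
    lead_rsid: str
    lead_pos: int
    lead_trait: str
    lead_p: float
    members: pd.DataFrame       # rsid, chrom, pos, trait, p, n_traits
    known_catalogue: bool = False
    known_reference: bool = False
    genes: list[str] = field(default_factory=list)

    @property
    def novel(self) -> bool:
        return not (self.known_catalogue or self.known_reference)

    @property
    def n_members(self) -> int:
        return len(self.members)


def collate_significant(gwas_tables: dict[str, pd.DataFrame],
                        threshold: float) -> pd.DataFrame:
    """Union of (variant, best trait, best P) pairs below the threshold.

    A variant significant for several traits keeps the trait with the
    smallest P and a count of significant traits.
    """
    if not gwas_tables:
        raise ValueError("need at least one GWAS table")
    frames = []
    for trait, tab in gwas_tables.items():
        hits = tab.loc[tab["p"] < threshold, ["rsid", "chr", "pos", "p"]].copy()
        hits["trait"] = trait
        frames.append(hits)
    pooled = pd.concat(frames, ignore_index=True)
    if pooled.empty:
        return pd.DataFrame(columns=["rsid", "chrom", "pos", "trait", "p", "n_traits"])
    pooled = pooled.rename(columns={"chr": "chrom"})
    counts = pooled.groupby("rsid")["trait"].nunique()
    best = pooled.sort_values("p", kind="stable").drop_duplicates("rsid")
    best["n_traits"] = best["rsid"].map(counts)
    return best.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def cluster_loci(signals: pd.DataFrame, gap: float = 1e6) -> list[Locus]:
    """Chain-link signals per chromosome: gaps <= ``gap`` join a locus."""
    loci: list[Locus] = []
    if signals is None or len(signals) == 0:
        return loci
    for chrom, sub in signals.groupby("chrom", sort=True):
        sub = sub.sort_values("pos", kind="stable").reset_index(drop=True)
        breaks = np.flatnonzero(np.diff(sub["pos"].to_numpy()) > gap) + 1
        for chunk in np.split(np.arange(len(sub)), breaks):
            members = sub.iloc[chunk].reset_index(drop=True)
            lead = members.loc[members["p"].idxmin()]
            loci.append(Locus(
                chrom=str(chrom),
                start=int(members["pos"].min()),
                end=int(members["pos"].max()),
                lead_rsid=str(lead["rsid"]),
                lead_pos=int(lead["pos"]),
                lead_trait=str(lead["trait"]),
                lead_p=float(lead["p"]),
                members=members,
            ))
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


def filter_known(loci: list[Locus], catalogue: pd.DataFrame | None = None,
                 reference_assoc: dict[str, pd.DataFrame] | None = None,
                 p_exclude: float = 1e-12, window: float = 1e6) -> list[Locus]:
    """Flag loci overlapping the known-association catalogue or reference hits.

    A locus is catalogue-known if any member lies within ``window`` of a
    catalogue entry on the same chromosome, and reference-known if any member
    reaches P < ``p_exclude`` in any reference (BMI/WHR-style) table.  Flags
    are set in place; the list is returned for chaining.
    """
    cat_by_chrom: dict[str, np.ndarray] = {}
    if catalogue is not None and len(catalogue):
        for col in ("chrom", "pos"):
            if col not in catalogue.columns:
                raise ValueError(f"catalogue lacks required column {col!r}")
        bad = catalogue["pos"].isna() | catalogue["chrom"].isna()
        if bad.any():
            lines = [str(i + 1) for i in catalogue.index[bad]]
            raise ValueError("malformed catalogue rows at lines: " + ", ".join(lines))
        for chrom, sub in catalogue.groupby("chrom"):
            cat_by_chrom[str(chrom)] = np.sort(sub["pos"].to_numpy(dtype=float))

    ref_lookup: dict[str, float] = {}
    for tab in (reference_assoc or {}).values():
        for rsid, p in zip(tab["rsid"], tab["p"]):
            ref_lookup[rsid] = min(p, ref_lookup.get(rsid, 1.0))

    for locus in loci:
        positions = cat_by_chrom.get(locus.chrom)
        if positions is not None and len(positions):
            mpos = locus.members["pos"].to_numpy(dtype=float)
            j = np.searchsorted(positions, mpos)
            nearest = np.full(len(mpos), np.inf)
            ok = j < len(positions)
            nearest[ok] = np.abs(positions[j[ok]] - mpos[ok])
            ok = j > 0
            nearest[ok] = np.minimum(nearest[ok], np.abs(positions[j[ok] - 1] - mpos[ok]))
            locus.known_catalogue = bool((nearest <= window).any())
        if ref_lookup:
            pmin = min((ref_lookup.get(r, 1.0) for r in locus.members["rsid"]), default=1.0)
            locus.known_reference = bool(pmin < p_exclude)
    return loci


def annotate_genes(locus: Locus, gene_table: pd.DataFrame,
                   flank: float = 5e5) -> list[str]:
    """Genes intersecting [lead - flank, lead + flank], closest first.

    Intervals are 1-based inclusive; a gene body containing the lead has
    distance 0.  The label list is also stored on the locus.
    """
    genes: list[tuple[float, str]] = []
    sub = gene_table[gene_table["chrom"].astype(str) == locus.chrom]
    lo, hi = locus.lead_pos - flank, locus.lead_pos + flank
    for _, row in sub.iterrows():
        if row["end"] >= lo and row["start"] <= hi:
            if row["start"] <= locus.lead_pos <= row["end"]:
                dist = 0.0
            else:
                dist = min(abs(row["start"] - locus.lead_pos), abs(row["end"] - locus.lead_pos))
            genes.append((dist, str(row["name"])))
    genes.sort()
    locus.genes = [g for _, g in genes]
    return locus.genes


def read_catalogue(path) -> pd.DataFrame:
    """Known-association catalogue TSV: chrom, pos (1-based), trait, source."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df


def read_gene_table(path, bed: bool = False) -> pd.DataFrame:
    """Gene annotation TSV (chrom, start, end, name; 1-based inclusive).

    With ``bed=True`` the file is 0-based half-open and converted on read.
    """
    if bed:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "name"], dtype={"chrom": str})
        df["start"] = df["start"] + 1
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df
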