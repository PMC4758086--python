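"""Input/output and shared table conventions.

All per-SNP tables carry 1-based coordinates in ``chrom``/``pos`` columns and
are sorted by ``(chrom, pos)`` (lexicographic on chromosome name).  Gene
intervals use the BED convention: 0-based, half-open.  The conversion between
the two happens in one place only — the annotation join.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger("poolscan")

VALID_GROUPS = ("highland", "lowland")

#: sync dialect column order within each population's count string
SYNC_BASE_ORDER = ("A", "T", "C", "G", "N", "del")


class ParseError(ValueError):
    """Malformed input file; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class PopulationMeta:
    """One pooled population: label, altitude group and pool composition."""

    name: str
    group: str
    altitude_m: float
    pool_size_n: int

    def __post_init__(self):
        if not self.name:
            raise ValueError("population name must be non-empty")
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"group {self.group!r} for population {self.name!r} is not one "
                f"of {VALID_GROUPS}"
            )
        if self.altitude_m < 0:
            raise ValueError(f"altitude_m must be non-negative ({self.name})")
        if int(self.pool_size_n) < 1:
            raise ValueError(f"pool_size_n must be >= 1 ({self.name})")


def validate_populations(populations: Sequence[PopulationMeta]) -> tuple[PopulationMeta, ...]:
    pops = tuple(populations)
    names = [p.name for p in pops]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate population names: {names}")
    return pops


def highland_names(populations: Sequence[PopulationMeta]) -> list[str]:
    return [p.name for p in populations if p.group == "highland"]


def lowland_names(populations: Sequence[PopulationMeta]) -> list[str]:
    return [p.name for p in populations if p.group == "lowland"]


@dataclass
class SnpCountTable:
    """Per-SNP, per-population reference/alternate read counts.

    ``frame`` columns: ``chrom, pos, ref, alt`` then ``<pop>_ref, <pop>_alt``
    for each population, in the order given by ``populations``.
    """

    frame: pd.DataFrame
    populations: tuple[PopulationMeta, ...]

    def __post_init__(self):
        self.populations = validate_populations(self.populations)
        self.frame = self.frame.reset_index(drop=True)
        self.validate()

    @property
    def n_snps(self) -> int:
        return len(self.frame)

    @property
    def pop_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def count_columns(self) -> list[str]:
        cols = []
        for name in self.pop_names:
            cols += [f"{name}_ref", f"{name}_alt"]
        return cols

    def validate(self) -> None:
        required = ["chrom", "pos", "ref", "alt"] + self.count_columns()
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        keys = self.frame[["chrom", "pos"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ValueError(f"duplicate SNP key ({dup['chrom']}, {dup['pos']})")
        if not keys.equals(keys.sort_values(["chrom", "pos"]).reset_index(drop=True)):
            raise ValueError("count table must be sorted by (chrom, pos)")
        counts = self.frame[self.count_columns()]
        if (counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    def depth(self) -> pd.DataFrame:
        """Per-population depth (ref + alt reads), one column per population."""
        return pd.DataFrame(
            {
                name: self.frame[f"{name}_ref"] + self.frame[f"{name}_alt"]
                for name in self.pop_names
            }
        )

    def keys(self) -> pd.DataFrame:
        return self.frame[["chrom", "pos"]].copy()

    def subset(self, mask) -> "SnpCountTable":
        return SnpCountTable(self.frame[mask].reset_index(drop=True), self.populations)


@dataclass
class GeneIntervalSet:
    """Gene intervals in BED convention (0-based, half-open)."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "gene_id"])
    )

    def __post_init__(self):
        self.frame = self.frame.reset_index(drop=True)
        bad = self.frame["start"] >= self.frame["end"] if len(self.frame) else pd.Series(dtype=bool)
        if len(self.frame) and bad.any():
            idx = int(bad.idxmax())
            raise ValueError(f"gene interval record {idx}: start >= end")
        if len(self.frame) and (self.frame["gene_id"].astype(str) == "").any():
            raise ValueError("gene_id must be non-empty")

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_population_meta(path) -> list[PopulationMeta]:
    """Read the population table (TSV: name, group, altitude_m, pool_size_n)."""
    df = pd.read_csv(path, sep="\t")
    required = ["name", "group", "altitude_m", "pool_size_n"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"population meta missing columns: {missing}")
    pops = [
        PopulationMeta(
            name=str(r["name"]),
            group=str(r["group"]),
            altitude_m=float(r["altitude_m"]),
            pool_size_n=int(r["pool_size_n"]),
        )
        for _, r in df.iterrows()
    ]
    validate_populations(pops)
    return pops


def write_population_meta(populations: Sequence[PopulationMeta], path) -> None:
    pd.DataFrame(
        [
            {
                "name": p.name,
                "group": p.group,
                "altitude_m": p.altitude_m,
                "pool_size_n": p.pool_size_n,
            }
            for p in populations
        ]
    ).to_csv(path, sep="\t", index=False)


def read_pool_counts(
    path,
    populations: Sequence[PopulationMeta],
    dialect: str = "native_tsv",
) -> SnpCountTable:
    """Read per-population read counts in the native TSV or sync dialect.

    In the sync dialect the two most frequent bases summed over all pools
    define ref/alt; sites with more than two observed bases are dropped (the
    number dropped is logged).
    """
    populations = validate_populations(populations)
    if dialect == "native_tsv":
        frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    elif dialect == "sync":
        frame = _read_sync(path, populations)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'native_tsv' or 'sync'")
    frame = frame.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    table = SnpCountTable(frame, populations)
    all_mono = (
        sum(table.frame[f"{n}_alt"] for n in table.pop_names) == 0
    )
    if all_mono.any():
        logger.info("%d sites have zero alt reads in every pool (kept)", int(all_mono.sum()))
    return table


def _read_sync(path, populations: Sequence[PopulationMeta]) -> pd.DataFrame:
    n_pops = len(populations)
    records = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3 + n_pops:
                raise ParseError(
                    f"expected {3 + n_pops} columns, found {len(fields)}", line=lineno
                )
            chrom, pos_s, declared_ref = fields[0], fields[1], fields[2].upper()
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"non-integer position {pos_s!r}", line=lineno) from None
            per_pool = []
            for col in fields[3:]:
                parts = col.split(":")
                if len(parts) != 6:
                    raise ParseError(f"bad sync count string {col!r}", line=lineno)
                try:
                    per_pool.append([int(x) for x in parts])
                except ValueError:
                    raise ParseError(f"bad sync count string {col!r}", line=lineno) from None
            # totals over pools for A,T,C,G (N and deletions never become alleles)
            totals = {b: sum(p[i] for p in per_pool) for i, b in enumerate(SYNC_BASE_ORDER[:4])}
            observed = [b for b in SYNC_BASE_ORDER[:4] if totals[b] > 0]
            if len(observed) > 2:
                n_dropped += 1
                continue
            ranked = sorted(totals, key=lambda b: (-totals[b], SYNC_BASE_ORDER.index(b)))
            ref = ranked[0] if observed else declared_ref
            alt = ranked[1] if len(observed) >= 2 else next(
                b for b in "ACGT" if b != ref
            )
            rec = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
            iref = SYNC_BASE_ORDER.index(ref)
            ialt = SYNC_BASE_ORDER.index(alt)
            for pop, counts in zip(populations, per_pool):
                rec[f"{pop.name}_ref"] = counts[iref]
                rec[f"{pop.name}_alt"] = counts[ialt]
            records.append(rec)
    if n_dropped:
        logger.info("sync reader dropped %d sites with >2 observed alleles", n_dropped)
    columns = ["chrom", "pos", "ref", "alt"] + [
        f"{p.name}_{k}" for p in populations for k in ("ref", "alt")
    ]
    return pd.DataFrame(records, columns=columns)


def write_pool_counts(table: SnpCountTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def repolarize_to_major(table: SnpCountTable, population: str) -> SnpCountTable:
    """Swap ref/alt so that ref is the major allele of ``population``.

    Mirrors the convention of anchoring the reference alleles to the major
    alleles of one focal population.  Differentiation statistics are invariant
    to this relabeling; it only affects the sign convention of frequencies.
    """
    if population not in table.pop_names:
        raise ValueError(f"unknown population {population!r}")
    frame = table.frame.copy()
    flip = frame[f"{population}_alt"] > frame[f"{population}_ref"]
    if flip.any():
        frame.loc[flip, ["ref", "alt"]] = frame.loc[flip, ["alt", "ref"]].to_numpy()
        for name in table.pop_names:
            cols = [f"{name}_ref", f"{name}_alt"]
            frame.loc[flip, cols] = frame.loc[flip, cols[::-1]].to_numpy()
    logger.info("repolarized %d sites to the %s major allele", int(flip.sum()), population)
    return SnpCountTable(frame, table.populations)


def read_gene_intervals(path) -> GeneIntervalSet:
    """Read BED3+name gene intervals (0-based, half-open)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "gene_id"],
            dtype={"chrom": str, "start": int, "end": int, "gene_id": str},
        )
    except pd.errors.EmptyDataError:
        return GeneIntervalSet()
    return GeneIntervalSet(df)


def write_gene_intervals(genes: GeneIntervalSet, path) -> None:
    genes.frame.to_csv(path, sep="\t", header=False, index=False)


def write_newick(tree, path) -> None:
    """Serialize a population tree as newick with branch lengths."""
    dtree = getattr(tree, "tree", tree)  # accept PopulationTree or dendropy.Tree
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree has an unnamed leaf; cannot serialize")
    text = dtree.as_string(schema="newick", suppress_rooting=True).strip()
    if not text.endswith(";"):
        text += ";"
    Path(path).write_text(text + "\n")


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
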