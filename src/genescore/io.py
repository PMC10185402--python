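"""Readers and writers tying the scoring modules into reproducible runs.

Inputs: GWAS summary statistics (delimited text with configurable column
names), gene annotation (GTF ``gene`` features or a 5-column TSV), gene sets
(GMT), and an optional variant-to-gene linking table.  Outputs are plain TSV
tables with a ``#``-prefixed provenance header (version, config hash, seed)
and a Benjamini-Hochberg adjusted-p convenience column.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from . import __version__
from .genes import GeneDef, SnpStat, SummaryStats
from .pathways import Pathway

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one scoring run."""

    panel_prefix: Optional[str] = None
    gwas: Optional[str] = None
    gwas2: Optional[str] = None
    annotation: Optional[str] = None
    gmt: Optional[str] = None
    linking: Optional[str] = None
    rscol: str = "rsid"
    pcol: str = "pval"
    bcol: Optional[str] = None
    a1col: Optional[str] = None
    a2col: Optional[str] = None
    window: int = 50_000
    fusion_window: Optional[int] = None
    maf_min: float = 0.0
    method: str = "auto"
    tails: str = "both"
    seed: int = 0
    workers: int = 1
    out_prefix: str = "genescore_out"

    def __post_init__(self):
        if self.workers < 1:
            raise ValueError("worker count must be >= 1")

    def validate_paths(self):
        for name in ("gwas", "gwas2", "annotation", "gmt", "linking"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    def hash(self) -> str:
        """Config digest for provenance.

        Excludes the worker count and output prefix: runs differing only in
        parallelism or destination must produce byte-identical tables.
        """
        d = {
            k: v for k, v in self.__dict__.items() if k not in ("workers", "out_prefix")
        }
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_summary_stats(
    path: str,
    rscol: str = "rsid",
    pcol: str = "pval",
    bcol: Optional[str] = None,
    a1col: Optional[str] = None,
    a2col: Optional[str] = None,
    sep: str = "\t",
) -> SummaryStats:
    """Read a delimited GWAS summary-statistics file.

    Rows with unparseable p-values are dropped and counted; duplicates keep
    the first occurrence; sub-floor p-values are clipped (all logged).
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    needed = [c for c in (rscol, pcol, bcol, a1col, a2col) if c is not None]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; available: {list(df.columns)}"
        )
    p = pd.to_numeric(df[pcol], errors="coerce")
    bad = p.isna() | (p <= 0) | (p > 1)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: dropped %d rows with invalid p-values", path, n_bad)
    df = df.loc[~bad]
    p = p.loc[~bad]

    def col(c):
        return df[c] if c is not None else [None] * len(df)

    items = (
        (
            str(v),
            SnpStat(
                float(pv),
                beta=None if b is None or pd.isna(b) else float(b),
                a1=None if a is None or pd.isna(a) else str(a),
                a2=None if o is None or pd.isna(o) else str(o),
            ),
        )
        for v, pv, b, a, o in zip(df[rscol], p, col(bcol), col(a1col), col(a2col))
    )
    stats = SummaryStats.from_records(items)
    logger.info("%s: %d variants retained", path, len(stats))
    return stats


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_annotation(path: str, fmt: str = "auto") -> List[GeneDef]:
    """Read gene definitions from GTF (``gene`` features) or 5-column TSV.

    TSV columns: gene_id, chrom, start, end, strand (header optional,
    detected).  Coordinates are 1-based inclusive in both formats.
    """
    if fmt == "auto":
        fmt = "gtf" if str(path).rstrip(".gz").endswith((".gtf", ".gff")) else "tsv"
    genes: List[GeneDef] = []
    if fmt == "gtf":
        with _open_text(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise ValueError(f"{path}:{ln}: expected 9 GTF columns")
                if parts[2] != "gene":
                    continue
                attrs = dict(_GTF_ATTR.findall(parts[8]))
                gid = attrs.get("gene_id")
                if gid is None:
                    raise ValueError(f"{path}:{ln}: gene feature without gene_id")
                try:
                    genes.append(
                        GeneDef(
                            gid,
                            attrs.get("gene_name", gid),
                            parts[0],
                            int(parts[3]),
                            int(parts[4]),
                            parts[6] if parts[6] in "+-" else "+",
                        )
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: {exc}") from exc
        return genes
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "gene_id":  # header
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected >= 4 TSV columns")
            try:
                genes.append(
                    GeneDef(
                        parts[0],
                        parts[0],
                        parts[1],
                        int(parts[2]),
                        int(parts[3]),
                        parts[4] if len(parts) > 4 and parts[4] in "+-" else "+",
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
    return genes


def read_gmt(path: str) -> List[Pathway]:
    """Read gene sets from GMT (name, description, member ids...)."""
    out = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT needs name, description, members")
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                raise ValueError(f"{path}:{ln}: gene set {parts[0]} has no members")
            out.append(Pathway(parts[0], members, parts[1]))
    return out


def read_linking(path: str) -> Dict[str, Set[str]]:
    """Read a variant-to-gene linking TSV (variant_id, gene_id)."""
    link: Dict[str, Set[str]] = {}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "variant_id":
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected variant_id<TAB>gene_id")
            link.setdefault(parts[0], set()).add(parts[1])
    return link


def _bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (NaN-aware)."""
    from statsmodels.stats.multitest import multipletests

    out = pd.Series(np.nan, index=p.index)
    mask = p.notna()
    if mask.any():
        out.loc[mask] = multipletests(p[mask].to_numpy(), method="fdr_bh")[1]
    return out


def write_table(
    df: pd.DataFrame,
    path: str,
    config: Optional[RunConfig] = None,
    pcol: str = "p",
) -> None:
    """Write a TSV with provenance header and a BH-adjusted p column."""
    df = df.copy()
    if pcol in df.columns:
        df[f"{pcol}_bh"] = _bh_adjust(df[pcol])
    with open(path, "w") as fh:
        fh.write(f"# genescore {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash={config.hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
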