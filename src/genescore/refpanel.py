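"""Indexed reference-panel genotype store and local LD correlation matrices.

Gene scoring needs fast random access to reference-panel genotypes by genomic
position and by variant id.  ``import_vcf`` converts a (plain or gzipped) VCF
into one store per chromosome; only the index lives in memory and genotype
payloads are decoded lazily from disk.

Store format (versioned, portable)
----------------------------------
``<prefix>.chr<k>.dat``
    Concatenation of per-variant records, each a zlib-compressed blob of::

        magic   b"GR01"
        u16     len(variant_id)   + utf-8 bytes
        u16     len(ref_allele)   + utf-8 bytes
        u16     len(alt_allele)   + utf-8 bytes
        u32     pos (1-based)
        u32     n_samples
        u8[n]   dosages, 0/1/2 alt-allele counts, 255 = missing

    (little-endian integers throughout).

``<prefix>.chr<k>.idx``
    JSON: ``{"magic": "GSPANEL", "version": 1, "chrom": ..., "samples":
    [...], "variants": [[id, pos, offset, length], ...]}`` with variants
    sorted by position.
"""

from __future__ import annotations

import json
import logging
import struct
import zlib
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

_MAGIC = b"GR01"
_IDX_MAGIC = "GSPANEL"
_VERSION = 1
MISSING = 255


@dataclass
class PanelRecord:
    """One biallelic reference-panel variant with per-sample dosages."""

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    dosages: np.ndarray  # uint8, alt-allele counts, 255 = missing

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based coordinates)")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        self.dosages = np.asarray(self.dosages, dtype=np.uint8)

    def to_bytes(self) -> bytes:
        vid = self.variant_id.encode()
        ref = self.ref_allele.encode()
        alt = self.alt_allele.encode()
        raw = b"".join(
            [
                _MAGIC,
                struct.pack("<H", len(vid)),
                vid,
                struct.pack("<H", len(ref)),
                ref,
                struct.pack("<H", len(alt)),
                alt,
                struct.pack("<II", self.pos, self.dosages.size),
                self.dosages.tobytes(),
            ]
        )
        return zlib.compress(raw)

    @classmethod
    def from_bytes(cls, blob: bytes, chrom: str) -> "PanelRecord":
        raw = zlib.decompress(blob)
        if raw[:4] != _MAGIC:
            raise ValueError("corrupt panel record (bad magic)")
        off = 4
        fields = []
        for _ in range(3):
            (n,) = struct.unpack_from("<H", raw, off)
            off += 2
            fields.append(raw[off : off + n].decode())
            off += n
        pos, nsamp = struct.unpack_from("<II", raw, off)
        off += 8
        dosages = np.frombuffer(raw, dtype=np.uint8, count=nsamp, offset=off).copy()
        return cls(fields[0], chrom, pos, fields[1], fields[2], dosages)


class PanelStore:
    """Random-access view over per-chromosome panel files.

    Picklable (file handles are reopened lazily per process), so stores can be
    shipped to worker processes for per-gene parallel scoring.
    """

    def __init__(self, prefix: str):
        self.prefix = str(prefix)
        self.samples: List[str] = []
        self._index: Dict[str, dict] = {}  # chrom -> {ids, pos, offsets, lengths}
        self._handles: Dict[str, object] = {}
        self._unknown_chroms_logged: set = set()
        self._load_indices()

    # -- construction -------------------------------------------------------

    def _load_indices(self):
        base = Path(self.prefix)
        pattern = base.name + ".chr*.idx"
        for idx_path in sorted(base.parent.glob(pattern)):
            with open(idx_path) as fh:
                meta = json.load(fh)
            if meta.get("magic") != _IDX_MAGIC or meta.get("version") != _VERSION:
                raise ValueError(f"{idx_path}: not a version-{_VERSION} panel index")
            chrom = meta["chrom"]
            if self.samples and meta["samples"] != self.samples:
                raise ValueError("inconsistent sample lists across chromosomes")
            self.samples = meta["samples"]
            variants = meta["variants"]
            self._index[chrom] = {
                "ids": {v[0]: i for i, v in enumerate(variants)},
                "pos": np.array([v[1] for v in variants], dtype=np.int64),
                "offsets": [(v[2], v[3]) for v in variants],
                "vids": [v[0] for v in variants],
            }

    def __getstate__(self):
        state = self.__dict__.copy()
        state["_handles"] = {}
        return state

    # -- queries ------------------------------------------------------------

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._index)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def n_variants(self, chrom: Optional[str] = None) -> int:
        if chrom is not None:
            return len(self._index.get(chrom, {}).get("vids", []))
        return sum(len(v["vids"]) for v in self._index.values())

    def _handle(self, chrom: str):
        fh = self._handles.get(chrom)
        if fh is None:
            fh = open(f"{self.prefix}.chr{chrom}.dat", "rb")
            self._handles[chrom] = fh
        return fh

    def _fetch(self, chrom: str, i: int) -> PanelRecord:
        offset, length = self._index[chrom]["offsets"][i]
        fh = self._handle(chrom)
        fh.seek(offset)
        return PanelRecord.from_bytes(fh.read(length), chrom)

    def query_range(self, chrom: str, start: int, end: int) -> List[PanelRecord]:
        """All retained variants with start <= pos <= end, in position order."""
        if start > end:
            raise ValueError("start must be <= end")
        idx = self._index.get(chrom)
        if idx is None:
            if chrom not in self._unknown_chroms_logged:
                logger.warning("chromosome %s not in panel; returning no variants", chrom)
                self._unknown_chroms_logged.add(chrom)
            return []
        lo = bisect_left(idx["pos"].tolist(), start)
        hi = bisect_right(idx["pos"].tolist(), end)
        return [self._fetch(chrom, i) for i in range(lo, hi)]

    def query_ids(self, chrom: str, variant_ids: Iterable[str]) -> List[PanelRecord]:
        """Records for the given ids on one chromosome, in position order."""
        idx = self._index.get(chrom)
        if idx is None:
            return []
        found = sorted(idx["ids"][v] for v in variant_ids if v in idx["ids"])
        return [self._fetch(chrom, i) for i in found]

    def get(self, variant_id: str) -> Optional[PanelRecord]:
        for chrom, idx in self._index.items():
            i = idx["ids"].get(variant_id)
            if i is not None:
                return self._fetch(chrom, i)
        return None

    def variant_positions(self, chrom: str) -> np.ndarray:
        idx = self._index.get(chrom)
        return idx["pos"].copy() if idx is not None else np.array([], dtype=np.int64)

    def close(self):
        for fh in self._handles.values():
            fh.close()
        self._handles = {}


def import_vcf(
    vcf_path: str,
    out_prefix: str,
    maf_min: float = 0.0,
    missing_max: float = 0.05,
    keep_samples: Optional[Sequence[str]] = None,
) -> PanelStore:
    """Import a biallelic VCF into the indexed per-chromosome store.

    Variants with minor-allele frequency below ``maf_min`` or missing-genotype
    rate above ``missing_max`` are excluded; multi-allelic records are skipped
    with a warning.  Duplicate variant ids: last occurrence wins (logged).
    Returns the opened :class:`PanelStore`.
    """
    from cyvcf2 import VCF

    if not (0.0 <= maf_min < 0.5):
        raise ValueError("maf_min must lie in [0, 0.5)")
    vcf = VCF(vcf_path, gts012=True)
    if keep_samples is not None:
        vcf.set_samples(list(keep_samples))
    samples = list(vcf.samples)

    out_prefix = str(out_prefix)
    writers: Dict[str, object] = {}
    entries: Dict[str, Dict[str, list]] = {}  # chrom -> vid -> [pos, offset, len]
    n_skipped = {"multiallelic": 0, "maf": 0, "missing": 0}
    try:
        for var in vcf:
            if len(var.ALT) != 1:
                n_skipped["multiallelic"] += 1
                logger.warning(
                    "skipping multi-allelic record %s:%d", var.CHROM, var.POS
                )
                continue
            gt = np.asarray(var.gt_types, dtype=np.int16)  # 0/1/2, 3=missing
            dosages = np.where(gt == 3, MISSING, gt).astype(np.uint8)
            valid = dosages != MISSING
            n_valid = int(valid.sum())
            if n_valid == 0 or 1.0 - n_valid / dosages.size > missing_max:
                n_skipped["missing"] += 1
                continue
            af = float(dosages[valid].sum()) / (2.0 * n_valid)
            maf = min(af, 1.0 - af)
            if maf < maf_min:
                n_skipped["maf"] += 1
                continue
            vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
            rec = PanelRecord(vid, var.CHROM, var.POS, var.REF, var.ALT[0], dosages)
            chrom = var.CHROM
            if chrom not in writers:
                writers[chrom] = open(f"{out_prefix}.chr{chrom}.dat", "wb")
                entries[chrom] = {}
            blob = rec.to_bytes()
            fh = writers[chrom]
            offset = fh.tell()
            fh.write(blob)
            if vid in entries[chrom]:
                logger.warning("duplicate variant id %s: keeping last occurrence", vid)
            entries[chrom][vid] = [rec.pos, offset, len(blob)]
    finally:
        for fh in writers.values():
            fh.close()
        vcf.close()

    for chrom, ents in entries.items():
        variants = sorted(
            ([vid, pos, off, ln] for vid, (pos, off, ln) in ents.items()),
            key=lambda v: (v[1], v[0]),
        )
        meta = {
            "magic": _IDX_MAGIC,
            "version": _VERSION,
            "chrom": chrom,
            "samples": samples,
            "variants": variants,
        }
        with open(f"{out_prefix}.chr{chrom}.idx", "w") as fh:
            json.dump(meta, fh)
    if not entries:  # valid empty store: write an empty placeholder index? no files
        logger.info("VCF %s contained no importable variants", vcf_path)
    logger.info("import_vcf: skipped %s", n_skipped)
    return PanelStore(out_prefix)


def dosage_matrix(records: Sequence[PanelRecord]) -> np.ndarray:
    """(n_variants, n_samples) float matrix with missing entries mean-imputed."""
    x = np.stack([r.dosages for r in records]).astype(float)
    miss = x == MISSING
    if miss.any():
        x[miss] = np.nan
        means = np.nanmean(x, axis=1)
        rows = np.where(miss.any(axis=1))[0]
        for i in rows:
            x[i, np.isnan(x[i])] = means[i]
    return x


def correlation_matrix(
    records: Sequence[PanelRecord],
) -> Tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of dosage vectors, after mean-imputation.

    Monomorphic variants (zero variance) are dropped; returns ``(sigma,
    kept_indices)`` where ``kept_indices`` refers to positions in ``records``.
    An all-monomorphic input yields a 0x0 matrix (callers treat it as an
    unscorable gene).
    """
    if not records:
        raise ValueError("correlation_matrix needs at least one record")
    x = dosage_matrix(records)
    sd = x.std(axis=1)
    kept = np.where(sd > 0)[0]
    if kept.size == 0:
        return np.empty((0, 0)), kept
    sigma = np.corrcoef(x[kept])
    sigma = np.atleast_2d(sigma)
    np.fill_diagonal(sigma, 1.0)
    return sigma, kept
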