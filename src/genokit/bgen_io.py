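"""BGEN v1.2 writer/reader with a separate random-access index.

Implements the layout-2 subset that biobank-scale imputed data uses in
practice: biallelic variants, diploid (optionally phased, optionally
haploid) samples, B-bit packed probabilities (default 8), zlib-compressed
genotype blocks (or uncompressed).  Multi-allelic records and layout 1
are refused.

Probabilities are quantized to integers summing exactly to 2^B - 1 per
sample (per haplotype when phased) by round-down plus largest-remainder
distribution (ties to the earlier probability), the last value of each
sample implied by the sum constraint and omitted from the stream.  Bits
are packed little-endian into one continuous stream, so a round trip
reproduces every probability to within 1 / (2^B - 1).

The companion index is a plain TSV of (chrom, pos, id, rsid, offset,
size) sorted by chromosome and position; ``query_region`` reads only the
blocks whose positions fall in the requested 1-based inclusive interval.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MAGIC = b"bgen"
COMPRESSION_CODES = {"none": 0, "zlib": 1}
_CODE_TO_COMPRESSION = {v: k for k, v in COMPRESSION_CODES.items()}


class BgenFormatError(ValueError):
    pass


class BgenIntegrityError(IOError):
    pass


@dataclass
class BgenDataset:
    path: str
    n_samples: int
    n_variants: int
    compression: str
    sample_ids: list
    index: pd.DataFrame   # chrom, pos, id, rsid, offset, size

    @property
    def index_path(self) -> str:
        return str(self.path) + ".idx.tsv"


# ---------------------------------------------------------------------------
# quantization and bit packing
# ---------------------------------------------------------------------------

def quantize_probs(p: np.ndarray, bits: int) -> np.ndarray:
    """Map probability vectors (rows) to integers summing to 2^B - 1.

    Round-down then distribute the leftover units to the largest
    fractional remainders (ties to the earlier entry).
    """
    total = (1 << bits) - 1
    p = np.asarray(p, dtype=float)
    p = p / p.sum(axis=-1, keepdims=True)
    scaled = p * total
    base = np.floor(scaled).astype(np.int64)
    short = total - base.sum(axis=-1)
    frac = scaled - base
    # stable argsort descending on fraction -> ties broken by lower index
    order = np.argsort(-frac, axis=-1, kind="stable")
    out = base.copy()
    for row in range(out.shape[0]):
        for r in range(int(short[row])):
            out[row, order[row, r]] += 1
    return out


def _pack_bits(values: np.ndarray, bits: int) -> bytes:
    """Pack unsigned ints little-endian into a continuous bitstream."""
    buf = bytearray()
    acc = 0
    nbits = 0
    for v in values:
        acc |= int(v) << nbits
        nbits += bits
        while nbits >= 8:
            buf.append(acc & 0xFF)
            acc >>= 8
            nbits -= 8
    if nbits:
        buf.append(acc & 0xFF)
    return bytes(buf)


def _unpack_bits(data: bytes, bits: int, count: int) -> np.ndarray:
    out = np.empty(count, dtype=np.int64)
    acc = 0
    nbits = 0
    pos = 0
    mask = (1 << bits) - 1
    for k in range(count):
        while nbits < bits:
            acc |= data[pos] << nbits
            pos += 1
            nbits += 8
        out[k] = acc & mask
        acc >>= bits
        nbits -= bits
    return out


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _encode_genotype_block(probs_row: np.ndarray, ploidy: np.ndarray,
                           phased: bool, bits: int) -> bytes:
    """Uncompressed layout-2 genotype data for one variant.

    ``probs_row``: (n_samples, 3) unphased genotype probabilities, or
    (n_samples, 2, 2) per-haplotype allele probabilities when phased.
    NaN rows mark missing samples.
    """
    n = probs_row.shape[0]
    out = bytearray()
    out += struct.pack("<IHBB", n, 2, int(ploidy.min()), int(ploidy.max()))
    missing = np.array([not np.all(np.isfinite(probs_row[s])) for s in range(n)])
    for s in range(n):
        out.append((0x80 if missing[s] else 0) | int(ploidy[s]))
    out += struct.pack("<BB", 1 if phased else 0, bits)

    values = []
    for s in range(n):
        if phased:
            for h in range(int(ploidy[s])):
                if missing[s]:
                    values.append(0)
                else:
                    q = quantize_probs(probs_row[s, h][None, :], bits)[0]
                    values.extend(q[:-1])
        else:
            n_probs = int(ploidy[s]) + 1          # biallelic: ploidy+1 genotypes
            if missing[s]:
                values.extend([0] * (n_probs - 1))
            else:
                vec = probs_row[s, :3] if ploidy[s] == 2 \
                    else probs_row[s, [0, 2]]     # haploid: (ref, alt)
                q = quantize_probs(np.asarray(vec)[None, :], bits)[0]
                values.extend(q[:-1])
    out += _pack_bits(np.array(values, dtype=np.int64), bits)
    return bytes(out)


def write_bgen(path, probs: np.ndarray, sample_ids, variants: pd.DataFrame,
               bits: int = 8, compression: str = "zlib", phased: bool = False,
               ploidy: np.ndarray | None = None) -> BgenDataset:
    """Write a BGEN v1.2 (layout 2) file plus its TSV index.

    ``probs`` is (n_samples, n_variants, 3) genotype probabilities
    (unphased) or (n_samples, n_variants, 2, 2) per-haplotype allele
    probabilities (phased).  ``variants`` needs columns id, rsid, chrom,
    pos, ref, alt (``rsid`` falls back to id).  NaN rows encode missing
    samples.  Returns the dataset handle with the in-memory index.
    """
    if not 1 <= bits <= 32:
        raise BgenFormatError("bits must be in [1, 32]")
    if compression not in COMPRESSION_CODES:
        raise BgenFormatError(f"unsupported compression {compression!r}")
    probs = np.asarray(probs, dtype=float)
    n_samples = probs.shape[0]
    n_variants = probs.shape[1]
    if len(variants) != n_variants:
        raise BgenFormatError("variants table length mismatch")
    if "rsid" not in variants.columns:
        variants = variants.assign(rsid=variants["id"])
    sample_ids = [str(s) for s in sample_ids]
    if len(sample_ids) != n_samples:
        raise BgenFormatError("sample id count mismatch")
    if ploidy is None:
        ploidy = np.full(n_samples, 2, dtype=int)

    sample_block = bytearray()
    body = bytearray()
    for s in sample_ids:
        b = s.encode()
        sample_block += struct.pack("<H", len(b)) + b
    sample_block = struct.pack("<II", 8 + len(sample_block), n_samples) + sample_block

    # header block: LH, M, N, magic, flags (no free data)
    flags = COMPRESSION_CODES[compression] | (2 << 2) | (1 << 31)
    header_block = struct.pack("<III", 20, n_variants, n_samples) + MAGIC \
        + struct.pack("<I", flags)
    offset = len(header_block) + len(sample_block)

    index_rows = []
    for j, row in enumerate(variants.itertuples(index=False)):
        if not isinstance(row.ref, str) or not isinstance(row.alt, str):
            raise BgenFormatError("alleles must be strings")
        vid, rsid, chrom = str(row.id).encode(), str(row.rsid).encode(), str(row.chrom).encode()
        block = bytearray()
        block += struct.pack("<H", len(vid)) + vid
        block += struct.pack("<H", len(rsid)) + rsid
        block += struct.pack("<H", len(chrom)) + chrom
        block += struct.pack("<I", int(row.pos))
        alleles = [str(row.ref).encode(), str(row.alt).encode()]
        block += struct.pack("<H", len(alleles))
        for a in alleles:
            block += struct.pack("<I", len(a)) + a
        geno = _encode_genotype_block(probs[:, j], ploidy, phased, bits)
        if compression == "zlib":
            comp = zlib.compress(geno)
            block += struct.pack("<I", len(comp) + 4) + struct.pack("<I", len(geno)) + comp
        else:
            block += struct.pack("<I", len(geno)) + geno
        var_offset = 4 + offset + len(body)      # absolute file offset
        body += block
        index_rows.append((row.chrom, int(row.pos), str(row.id), str(row.rsid),
                           var_offset, len(block)))

    with open(path, "wb") as fh:
        fh.write(struct.pack("<I", offset))
        fh.write(header_block)
        fh.write(bytes(sample_block))
        fh.write(bytes(body))

    index = pd.DataFrame(index_rows,
                         columns=["chrom", "pos", "id", "rsid", "offset", "size"])
    index = index.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    ds = BgenDataset(path=str(path), n_samples=n_samples, n_variants=n_variants,
                     compression=compression, sample_ids=sample_ids, index=index)
    index.to_csv(ds.index_path, sep="\t", index=False)
    return ds


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _decode_genotype_block(data: bytes, variant_name: str):
    try:
        n, k, _minp, _maxp = struct.unpack_from("<IHBB", data, 0)
        if k != 2:
            raise BgenFormatError("only biallelic records are supported")
        ploidy_bytes = np.frombuffer(data, dtype=np.uint8, count=n, offset=8)
        phased, bits = struct.unpack_from("<BB", data, 8 + n)
        stream = data[10 + n:]
        ploidy = (ploidy_bytes & 0x3F).astype(int)
        missing = (ploidy_bytes & 0x80) != 0
        if phased:
            counts = ploidy  # (K-1) values per haplotype
        else:
            counts = ploidy  # (ploidy+1 combinations) - 1 stored
        total_values = int(counts.sum())
        values = _unpack_bits(stream, bits, total_values)
    except (struct.error, IndexError) as exc:
        raise BgenIntegrityError(
            f"truncated or corrupt genotype block at variant {variant_name}"
        ) from exc
    denom = float((1 << bits) - 1)
    if phased:
        out = np.full((n, 2, 2), np.nan)
        pos = 0
        for s in range(n):
            for h in range(ploidy[s]):
                p_ref = values[pos] / denom
                pos += 1
                if not missing[s]:
                    out[s, h] = (p_ref, 1.0 - p_ref)
        return out, True, bits, ploidy, missing
    out = np.full((n, 3), np.nan)
    pos = 0
    for s in range(n):
        stored = values[pos:pos + ploidy[s]]
        pos += ploidy[s]
        if missing[s]:
            continue
        probs = stored / denom
        if ploidy[s] == 2:
            out[s] = (probs[0], probs[1], 1.0 - probs.sum())
        elif ploidy[s] == 1:   # haploid: hom-ref / hom-alt
            out[s] = (probs[0], 0.0, 1.0 - probs[0])
        else:
            raise BgenFormatError("only haploid/diploid samples are supported")
    return out, False, bits, ploidy, missing


def _read_header(fh):
    offset, = struct.unpack("<I", fh.read(4))
    lh, n_variants, n_samples = struct.unpack("<III", fh.read(12))
    magic = fh.read(4)
    if magic != MAGIC:
        raise BgenFormatError("not a BGEN file (bad magic)")
    fh.read(lh - 20)  # free data
    flags, = struct.unpack("<I", fh.read(4))
    compression_code = flags & 0x3
    layout = (flags >> 2) & 0xF
    has_samples = bool(flags >> 31)
    if layout != 2:
        raise BgenFormatError(f"unsupported layout {layout} (only layout 2)")
    if compression_code not in _CODE_TO_COMPRESSION:
        raise BgenFormatError(f"unsupported compression code {compression_code}")
    sample_ids = []
    if has_samples:
        _lsi, n2 = struct.unpack("<II", fh.read(8))
        for _ in range(n2):
            ln, = struct.unpack("<H", fh.read(2))
            sample_ids.append(fh.read(ln).decode())
    return offset, n_variants, n_samples, _CODE_TO_COMPRESSION[compression_code], sample_ids


def _read_variant_block(fh, compression):
    pos0 = fh.tell()
    head = fh.read(2)
    if len(head) < 2:
        return None
    ln, = struct.unpack("<H", head)
    vid = fh.read(ln).decode()
    ln, = struct.unpack("<H", fh.read(2))
    rsid = fh.read(ln).decode()
    ln, = struct.unpack("<H", fh.read(2))
    chrom = fh.read(ln).decode()
    pos, = struct.unpack("<I", fh.read(4))
    k, = struct.unpack("<H", fh.read(2))
    if k != 2:
        raise BgenFormatError("only biallelic records are supported")
    alleles = []
    for _ in range(k):
        la, = struct.unpack("<I", fh.read(4))
        alleles.append(fh.read(la).decode())
    c, = struct.unpack("<I", fh.read(4))
    payload = fh.read(c)
    if len(payload) < c:
        raise BgenIntegrityError(f"truncated block at variant {vid}")
    if compression == "zlib":
        d, = struct.unpack_from("<I", payload, 0)
        try:
            geno = zlib.decompress(payload[4:])
        except zlib.error as exc:
            raise BgenIntegrityError(f"corrupt compressed block at {vid}") from exc
        if len(geno) != d:
            raise BgenIntegrityError(f"bad uncompressed length at {vid}")
    else:
        geno = payload
    decoded = _decode_genotype_block(geno, vid)
    meta = {"id": vid, "rsid": rsid, "chrom": chrom, "pos": int(pos),
            "ref": alleles[0], "alt": alleles[1],
            "offset": pos0, "size": fh.tell() - pos0}
    return meta, decoded


def read_bgen(path):
    """Read a supported BGEN file.

    Returns ``(probs, sample_ids, variants, phased)`` where probs is
    (n_samples, n_variants, 3) for unphased data or
    (n_samples, n_variants, 2, 2) for phased data, NaN marking missing.
    """
    with open(path, "rb") as fh:
        _offset, n_variants, n_samples, compression, sample_ids = _read_header(fh)
        metas, blocks = [], []
        phased = False
        for _ in range(n_variants):
            item = _read_variant_block(fh, compression)
            if item is None:
                raise BgenIntegrityError("file ends before declared variant count")
            meta, (arr, phased, _bits, _pl, _miss) = item
            metas.append(meta)
            blocks.append(arr)
    variants = pd.DataFrame(metas)
    probs = np.stack(blocks, axis=1)
    return probs, sample_ids, variants, phased


def open_bgen(path) -> BgenDataset:
    """Open a BGEN file handle with its index (built by full scan if absent)."""
    idx_path = Path(str(path) + ".idx.tsv")
    with open(path, "rb") as fh:
        _offset, n_variants, n_samples, compression, sample_ids = _read_header(fh)
    if idx_path.exists():
        index = pd.read_csv(idx_path, sep="\t", dtype={"chrom": str})
    else:
        rows = []
        with open(path, "rb") as fh:
            _read_header(fh)
            for _ in range(n_variants):
                meta, _ = _read_variant_block(fh, compression)
                rows.append({k: meta[k] for k in
                             ("chrom", "pos", "id", "rsid", "offset", "size")})
        index = pd.DataFrame(rows).sort_values(["chrom", "pos"], kind="stable")
        index.to_csv(idx_path, sep="\t", index=False)
    return BgenDataset(path=str(path), n_samples=n_samples, n_variants=n_variants,
                       compression=compression, sample_ids=sample_ids,
                       index=index.reset_index(drop=True))


def query_region(dataset: BgenDataset, chrom, start: int, end: int):
    """Decode exactly the variants with position in [start, end] (1-based, inclusive).

    Returns (probs, variants) restricted to the interval, in position order.
    """
    if start > end:
        raise ValueError("inverted interval")
    idx = dataset.index
    hits = idx[(idx["chrom"].astype(str) == str(chrom))
               & (idx["pos"] >= start) & (idx["pos"] <= end)]
    metas, blocks = [], []
    with open(dataset.path, "rb") as fh:
        for off in hits["offset"]:
            fh.seek(int(off))
            meta, (arr, _ph, _b, _pl, _miss) = _read_variant_block(fh, dataset.compression)
            metas.append(meta)
            blocks.append(arr)
    if not blocks:
        n = dataset.n_samples
        return np.empty((n, 0, 3)), pd.DataFrame(
            columns=["id", "rsid", "chrom", "pos", "ref", "alt", "offset", "size"])
    return np.stack(blocks, axis=1), pd.DataFrame(metas)
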