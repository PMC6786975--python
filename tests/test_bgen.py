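"""BGEN v1.2 codec: quantization, round trips, golden bytes, region queries."""

import struct
import zlib

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genokit import bgen_io
from genokit.bgen_io import (BgenFormatError, BgenIntegrityError, open_bgen,
                             query_region, quantize_probs, read_bgen, write_bgen)


def _variants(n, chrom="1", start=1000, spacing=1000):
    return pd.DataFrame({
        "id": [f"v{i}" for i in range(n)], "rsid": [f"rs{i}" for i in range(n)],
        "chrom": chrom, "pos": start + spacing * np.arange(n),
        "ref": "A", "alt": "G"})


def _random_probs(rng, n_samples, n_variants):
    raw = rng.random((n_samples, n_variants, 3))
    return raw / raw.sum(-1, keepdims=True)


class TestQuantization:
    def test_vertex_probability_is_exact(self):
        q = quantize_probs(np.array([[1.0, 0.0, 0.0]]), 8)
        assert q.tolist() == [[255, 0, 0]]

    def test_rows_sum_to_full_scale(self, rng):
        p = _random_probs(rng, 200, 1)[:, 0, :]
        for bits in (1, 4, 8, 16):
            q = quantize_probs(p, bits)
            assert (q.sum(axis=1) == (1 << bits) - 1).all()
            assert (q >= 0).all()

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.001, 1.0), min_size=3, max_size=3),
           st.sampled_from([1, 2, 8, 12, 16]))
    def test_quantization_error_bounded(self, raw, bits):
        p = np.array(raw) / np.sum(raw)
        q = quantize_probs(p[None, :], bits)[0]
        denom = (1 << bits) - 1
        assert np.abs(q / denom - p).max() <= 1.0 / denom


class TestRoundTrip:
    @pytest.mark.parametrize("compression", ["zlib", "none"])
    @pytest.mark.parametrize("bits", [8, 16])
    def test_probabilities_survive_within_quantization(self, tmp_path, rng,
                                                       compression, bits):
        probs = _random_probs(rng, 7, 11)
        path = tmp_path / "t.bgen"
        write_bgen(path, probs, [f"S{i}" for i in range(7)], _variants(11),
                   bits=bits, compression=compression)
        got, sample_ids, variants, phased = read_bgen(path)
        assert not phased
        assert sample_ids == [f"S{i}" for i in range(7)]
        assert np.abs(got - probs).max() <= 1.0 / ((1 << bits) - 1)
        assert variants["pos"].tolist() == _variants(11)["pos"].tolist()

    def test_compression_transparency(self, tmp_path, rng):
        probs = _random_probs(rng, 4, 6)
        paths = {}
        for comp in ("zlib", "none"):
            p = tmp_path / f"{comp}.bgen"
            write_bgen(p, probs, list("abcd"), _variants(6), compression=comp)
            paths[comp] = read_bgen(p)[0]
        assert np.array_equal(paths["zlib"], paths["none"])

    def test_missing_samples_round_trip_as_nan(self, tmp_path, rng):
        probs = _random_probs(rng, 5, 3)
        probs[2, 1] = np.nan
        path = tmp_path / "m.bgen"
        write_bgen(path, probs, list("abcde"), _variants(3))
        got, *_ = read_bgen(path)
        assert np.isnan(got[2, 1]).all()
        assert np.isfinite(got[0]).all()

    def test_phased_haplotype_probabilities(self, tmp_path, rng):
        raw = rng.random((3, 4, 2, 2))
        probs = raw / raw.sum(-1, keepdims=True)
        path = tmp_path / "p.bgen"
        write_bgen(path, probs, list("abc"), _variants(4), phased=True)
        got, _sids, _vars, phased = read_bgen(path)
        assert phased
        assert got.shape == (3, 4, 2, 2)
        assert np.abs(got - probs).max() <= 1.0 / 255

    def test_haploid_samples(self, tmp_path):
        probs = np.zeros((2, 2, 3))
        probs[:, :, 0] = [[0.25], [1.0]]
        probs[:, :, 2] = [[0.75], [0.0]]
        path = tmp_path / "h.bgen"
        write_bgen(path, probs, ["m1", "m2"], _variants(2),
                   ploidy=np.array([1, 1]))
        got, *_ = read_bgen(path)
        assert np.abs(got - probs).max() <= 1.0 / 255
        assert (got[:, :, 1] == 0).all()


class TestGoldenBytes:
    def test_file_layout_matches_hand_encoding(self, tmp_path):
        """One sample, one variant, B=8, uncompressed: every byte derived
        by hand from the published layout-2 description."""
        probs = np.array([[[0.5, 0.25, 0.25]]])
        path = tmp_path / "g.bgen"
        write_bgen(path, probs, ["S1"], _variants(1), bits=8, compression="none")
        data = path.read_bytes()

        expect = bytearray()
        sample_block = struct.pack("<II", 8 + 4, 1) + struct.pack("<H", 2) + b"S1"
        expect += struct.pack("<I", 20 + len(sample_block))     # offset
        flags = 0 | (2 << 2) | (1 << 31)                        # none, layout 2, ids
        expect += struct.pack("<III", 20, 1, 1) + b"bgen" + struct.pack("<I", flags)
        expect += sample_block
        expect += struct.pack("<H", 2) + b"v0"
        expect += struct.pack("<H", 3) + b"rs0"
        expect += struct.pack("<H", 1) + b"1"
        expect += struct.pack("<I", 1000)
        expect += struct.pack("<H", 2)
        expect += struct.pack("<I", 1) + b"A" + struct.pack("<I", 1) + b"G"
        geno = struct.pack("<IHBB", 1, 2, 2, 2)                 # N, K, ploidy range
        geno += bytes([2])                                      # ploidy, not missing
        geno += struct.pack("<BB", 0, 8)                        # unphased, 8 bits
        # probabilities (0.5, 0.25, 0.25) -> (128, 63, 64) wait: by largest
        # remainder 0.5*255=127.5, 0.25*255=63.75 each; floors (127, 63, 63),
        # two units left -> the two largest remainders (.75, .75) at indices
        # 1, 2... index order ties first: fractions (0.5, 0.75, 0.75) ->
        # add to indices 1 and 2 -> (127, 64, 64); store first two.
        geno += bytes([127, 64])
        expect += struct.pack("<I", len(geno)) + geno
        assert data == bytes(expect)


class TestErrors:
    def test_truncated_file_raises_integrity_error(self, tmp_path, rng):
        probs = _random_probs(rng, 3, 5)
        path = tmp_path / "t.bgen"
        write_bgen(path, probs, list("abc"), _variants(5))
        data = path.read_bytes()
        bad = tmp_path / "bad.bgen"
        bad.write_bytes(data[:-20])
        with pytest.raises((BgenIntegrityError, BgenFormatError)):
            read_bgen(bad)

    def test_bad_magic_rejected(self, tmp_path):
        p = tmp_path / "x.bgen"
        p.write_bytes(b"\x00" * 4 + struct.pack("<III", 20, 0, 0) + b"nope"
                      + struct.pack("<I", 0))
        with pytest.raises(BgenFormatError):
            read_bgen(p)

    def test_invalid_bits_rejected(self, tmp_path, rng):
        with pytest.raises(BgenFormatError):
            write_bgen(tmp_path / "b.bgen", _random_probs(rng, 1, 1), ["a"],
                       _variants(1), bits=40)

    def test_corrupt_compressed_block(self, tmp_path, rng):
        probs = _random_probs(rng, 2, 1)
        path = tmp_path / "c.bgen"
        ds = write_bgen(path, probs, ["a", "b"], _variants(1))
        data = bytearray(path.read_bytes())
        off = int(ds.index["offset"].iloc[0])
        data[off + 40] ^= 0xFF  # clobber inside the compressed payload
        path.write_bytes(bytes(data))
        with pytest.raises((BgenIntegrityError, BgenFormatError)):
            read_bgen(path)


class TestRegionQueries:
    def test_empty_and_inverted_intervals(self, tmp_path, rng):
        probs = _random_probs(rng, 2, 5)
        path = tmp_path / "q.bgen"
        write_bgen(path, probs, ["a", "b"], _variants(5))
        ds = open_bgen(path)
        got, variants = query_region(ds, "1", 1, 10)
        assert variants.empty and got.shape[1] == 0
        with pytest.raises(ValueError):
            query_region(ds, "1", 100, 10)

    def test_full_interval_equals_full_scan(self, tmp_path, rng):
        probs = _random_probs(rng, 3, 20)
        path = tmp_path / "q.bgen"
        write_bgen(path, probs, list("abc"), _variants(20))
        ds = open_bgen(path)
        got, variants = query_region(ds, "1", 1, 10 ** 9)
        full, _sids, vfull, _ = read_bgen(path)
        assert np.array_equal(got, full)
        assert variants["id"].tolist() == vfull["id"].tolist()

    def test_random_intervals_match_brute_force(self, tmp_path, rng):
        n_var = 300
        probs = _random_probs(rng, 2, n_var)
        var = _variants(n_var, spacing=int(rng.integers(500, 1500)))
        path = tmp_path / "q.bgen"
        write_bgen(path, probs, ["a", "b"], var)
        ds = open_bgen(path)
        full, _s, vfull, _ = read_bgen(path)
        pos = vfull["pos"].to_numpy()
        for _ in range(25):
            a, b = sorted(rng.integers(0, pos.max() + 2000, size=2))
            got, variants = query_region(ds, "1", a, b)
            keep = (pos >= a) & (pos <= b)
            assert variants["pos"].tolist() == pos[keep].tolist()
            assert np.array_equal(got, full[:, keep])

    def test_index_rebuilt_when_absent(self, tmp_path, rng):
        probs = _random_probs(rng, 2, 4)
        path = tmp_path / "r.bgen"
        ds = write_bgen(path, probs, ["a", "b"], _variants(4))
        import os
        os.remove(ds.index_path)
        ds2 = open_bgen(path)
        got, variants = query_region(ds2, "1", 1000, 2000)
        assert variants["id"].tolist() == ["v0", "v1"]
        assert np.allclose(got, read_bgen(path)[0][:, :2], equal_nan=True)
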