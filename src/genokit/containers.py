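"""Core in-memory containers shared across the toolkit.

Genotypes are stored as an ``int8`` matrix of non-reference allele counts
(samples x markers) with ``-1`` encoding a missing call.  Marker and sample
metadata live in pandas DataFrames so they can round-trip through the
package's tabular dialect and through VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING = -1

MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]
SAMPLE_COLUMNS = ["sample_id", "batch", "plate", "array", "reported_sex", "inferred_sex"]


class CohortGenotypes:
    """A genotyped cohort: call matrix plus marker and sample metadata.

    Parameters
    ----------
    calls
        ``(n_samples, n_markers)`` int8 array of non-reference allele counts
        in ``{0, 1, 2}`` with ``-1`` for missing.
    markers
        DataFrame with columns ``id, chrom, pos, ref, alt`` (one row per
        marker, positions 1-based).
    samples
        DataFrame with columns ``sample_id, batch, plate, array,
        reported_sex, inferred_sex``.  Sexes are ``"M"``/``"F"`` (or ``""``
        when unknown).
    """

    def __init__(self, calls: np.ndarray, markers: pd.DataFrame, samples: pd.DataFrame):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples x markers array")
        if calls.shape != (len(samples), len(markers)):
            raise ValueError(
                f"calls shape {calls.shape} does not match metadata "
                f"({len(samples)} samples, {len(markers)} markers)"
            )
        for col in MARKER_COLUMNS:
            if col not in markers.columns:
                raise ValueError(f"markers missing column {col!r}")
        if "sample_id" not in samples.columns:
            raise ValueError("samples missing column 'sample_id'")
        self.calls = calls
        self.markers = markers.reset_index(drop=True)
        self.samples = samples.reset_index(drop=True)

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def copy(self) -> "CohortGenotypes":
        return CohortGenotypes(self.calls.copy(), self.markers.copy(), self.samples.copy())

    # -- summaries --------------------------------------------------------
    def alt_allele_frequency(self, sample_index=None) -> np.ndarray:
        """Non-reference allele frequency per marker over non-missing calls."""
        calls = self.calls if sample_index is None else self.calls[sample_index]
        obs = calls >= 0
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def maf(self, sample_index=None) -> np.ndarray:
        p = self.alt_allele_frequency(sample_index)
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, index) -> "CohortGenotypes":
        index = np.asarray(index)
        return CohortGenotypes(
            self.calls[:, index], self.markers.iloc[index], self.samples
        )

    def subset_samples(self, index) -> "CohortGenotypes":
        index = np.asarray(index)
        return CohortGenotypes(self.calls[index], self.markers, self.samples.iloc[index])

    # -- I/O ---------------------------------------------------------------
    def to_vcf(self, path) -> None:
        """Write calls as an uncompressed VCF with GT fields (``./.`` missing)."""
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=genokit\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(str(s) for s in self.samples["sample_id"])
                + "\n"
            )
            for j, row in enumerate(self.markers.itertuples(index=False)):
                gts = "\t".join(gt_codes[int(c)] for c in self.calls[:, j])
                fh.write(
                    f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                    f"\t.\t.\t.\tGT\t{gts}\n"
                )

    @classmethod
    def from_vcf(cls, path, samples: pd.DataFrame | None = None) -> "CohortGenotypes":
        """Read a GT-only VCF written by :meth:`to_vcf` (diploid, biallelic)."""
        marker_rows, call_rows, sample_ids = [], [], None
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    sample_ids = parts[9:]
                    continue
                chrom, pos, mid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
                marker_rows.append((mid, chrom, pos, ref, alt))
                row = []
                for gt in parts[9:]:
                    gt = gt.split(":")[0]
                    if "." in gt:
                        row.append(MISSING)
                    else:
                        row.append(sum(int(a) for a in gt.replace("|", "/").split("/")))
                call_rows.append(row)
        markers = pd.DataFrame(marker_rows, columns=MARKER_COLUMNS)
        calls = np.array(call_rows, dtype=np.int8).T
        if samples is None:
            samples = pd.DataFrame({"sample_id": sample_ids})
            for col in SAMPLE_COLUMNS[1:]:
                samples[col] = ""
        return cls(calls, markers, samples)


@dataclass
class ReferencePanel:
    """Phased reference haplotypes for one chromosome.

    ``haplotypes`` is an ``(n_haplotypes, n_sites)`` uint8 array of 0/1
    alleles; ``positions`` are strictly increasing 1-based base pairs.
    ``genetic_map`` optionally gives cumulative cM at each site.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    chrom: str = "1"
    ids: np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    genetic_map: np.ndarray | None = None

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("positions length must match number of sites")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("panel alleles must be 0/1")
        if self.ids is None:
            self.ids = np.array([f"m{i}" for i in range(len(self.positions))])
        if self.ref is None:
            self.ref = np.full(len(self.positions), "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(len(self.positions), "G", dtype=object)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def allele_frequency(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def to_vcf(self, path) -> None:
        """Write as a phased VCF (haplotype pairs -> pseudo-diploid samples)."""
        n_hap = self.n_haplotypes
        ids = [f"H{2*i}_{2*i+1}" for i in range((n_hap + 1) // 2)]
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##source=genokit\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(ids) + "\n"
            )
            for j in range(self.n_sites):
                gts = []
                for i in range(0, n_hap, 2):
                    a = self.haplotypes[i, j]
                    b = self.haplotypes[i + 1, j] if i + 1 < n_hap else "."
                    gts.append(f"{a}|{b}")
                fh.write(
                    f"{self.chrom}\t{self.positions[j]}\t{self.ids[j]}\t"
                    f"{self.ref[j]}\t{self.alt[j]}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "ReferencePanel":
        haps, positions, ids, refs, alts, chrom = [], [], [], [], [], "1"
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                chrom = parts[0]
                positions.append(int(parts[1]))
                ids.append(parts[2])
                refs.append(parts[3])
                alts.append(parts[4])
                alleles = []
                for gt in parts[9:]:
                    for a in gt.split(":")[0].split("|"):
                        if a != ".":
                            alleles.append(int(a))
                haps.append(alleles)
        return cls(
            np.array(haps, dtype=np.uint8).T,
            np.array(positions),
            chrom=chrom,
            ids=np.array(ids),
            ref=np.array(refs, dtype=object),
            alt=np.array(alts, dtype=object),
        )


class SparsePanelIndex:
    """Per-site carrier index of the reference panel.

    For each site, stores the sorted indices of haplotypes carrying the
    *minor* allele at that site, plus an orientation bit saying whether the
    stored carriers hold the non-reference allele (``True``) or the
    reference allele (``False``).  Reconstructing the dense matrix from the
    index reproduces it exactly.
    """

    def __init__(self, panel: ReferencePanel):
        self.n_haplotypes = panel.n_haplotypes
        self.n_sites = panel.n_sites
        self.carriers: list[np.ndarray] = []
        self.stores_alt: np.ndarray = np.ones(panel.n_sites, dtype=bool)
        for j in range(panel.n_sites):
            col = panel.haplotypes[:, j]
            alt_idx = np.flatnonzero(col == 1)
            if len(alt_idx) * 2 <= self.n_haplotypes:
                self.carriers.append(alt_idx.astype(np.int32))
                self.stores_alt[j] = True
            else:
                self.carriers.append(np.flatnonzero(col == 0).astype(np.int32))
                self.stores_alt[j] = False

    def alt_carriers(self, j: int) -> tuple[np.ndarray, bool]:
        """Return (stored carrier list, True if it lists ALT carriers)."""
        return self.carriers[j], bool(self.stores_alt[j])

    def to_dense(self) -> np.ndarray:
        out = np.zeros((self.n_haplotypes, self.n_sites), dtype=np.uint8)
        for j in range(self.n_sites):
            if self.stores_alt[j]:
                out[self.carriers[j], j] = 1
            else:
                out[:, j] = 1
                out[self.carriers[j], j] = 0
        return out


@dataclass
class TruthSet:
    """Ground truth emitted alongside simulated cohorts."""

    haplotypes: np.ndarray | None = None           # (n_samples, 2, n_sites)
    parents: dict = field(default_factory=dict)    # sample -> (father, mother) or None
    kinship: dict = field(default_factory=dict)    # frozenset({i, j}) -> phi
    karyotype: np.ndarray | None = None            # per-sample label
    causal_effects: dict = field(default_factory=dict)  # marker index -> beta
    masked_sites: np.ndarray | None = None         # site indices hidden for imputation truth
    artifact_markers: list = field(default_factory=list)

    def to_tsv(self, path) -> None:
        rows = [
            {"pair": ",".join(map(str, sorted(k))), "kinship": v}
            for k, v in self.kinship.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
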