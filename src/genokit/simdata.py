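"""Synthetic cohorts, reference panels, pedigrees, intensity clusters and phenotypes.

Every downstream stage of the toolkit is exercised against data from this
module, so it generates exactly the statistical structure those stages
assume:

* reference panels with linkage disequilibrium induced by a founder-mosaic
  copying process (each haplotype copies a founder and switches founders
  with a per-site probability) — seedable and desk-scale, *not* a
  population-genetic simulator;
* cohorts drawn from a panel by the same mosaic process, with symmetric
  genotype errors and per-batch call-level artifacts so the marker-QC
  battery has true positives;
* gene-dropping pedigree cohorts with known kinship per pair;
* X/Y mean-log2-ratio intensity clusters, one Gaussian per sex-chromosome
  karyotype;
* additive polygenic phenotypes with configurable heritability and
  covariate effects.

All operations are deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, CohortGenotypes, ReferencePanel, TruthSet


class ConfigurationError(ValueError):
    """Raised for degenerate or inconsistent simulation configurations."""


@dataclass
class ArtifactSpec:
    """A call-level artifact injected into one batch.

    ``kind`` is one of ``"het_to_homref"``, ``"het_to_homalt"``,
    ``"set_missing"``: within the named batch, the stated fraction of
    heterozygous (or, for ``set_missing``, all) calls at the listed marker
    indices is rewritten.
    """

    batch: str
    marker_indices: list
    kind: str = "het_to_homref"
    fraction: float = 0.3


@dataclass
class BatchSpec:
    batch: str
    plates: list
    array: str = "A"
    artifacts: list = field(default_factory=list)


#: Cluster centres in the (mean L2R X, mean L2R Y) plane per karyotype.
#: X copies move the first coordinate (log2 of copy number relative to 2),
#: Y copies move the second (relative to 1); absent chromosomes sit at a
#: background level.  Centres are fixed so karyotype calling is
#: deterministic and testable.
KARYOTYPE_CENTERS = {
    "XX": (0.0, -1.4),
    "XY": (-0.55, 0.0),
    "X0": (-0.55, -1.4),
    "XXX": (0.4, -1.4),
    "XXY": (0.0, 0.0),
    "XYY": (-0.55, 0.55),
}

KARYOTYPE_SEX = {"XX": "F", "XXX": "F", "X0": "F", "XY": "M", "XXY": "M", "XYY": "M"}


@dataclass
class SimConfig:
    """Configuration of the synthetic-data generator.

    Defaults are the study conditions assumed throughout the test-suite:
    a 20-founder mosaic panel, Beta(0.8, 0.8) site frequencies (U-shaped,
    so rare and common markers both occur), a 1-per-100-sites founder
    switch rate, and a 0.1% symmetric genotype error rate.
    """

    seed: int = 0
    n_founders: int = 20
    n_haplotypes: int = 200
    n_sites: int = 1000
    mosaic_switch_rate: float = 0.01
    allele_freq_shape: tuple = (0.8, 0.8)
    genotype_error_rate: float = 0.001
    batch_spec: list = field(default_factory=list)
    aneuploidy_mix: dict = field(default_factory=lambda: {"XX": 0.5, "XY": 0.5})
    l2r_sd: float = 0.07
    sex_mismatch_fraction: float = 0.0
    position_spacing: int = 1000

    def __post_init__(self):
        for name in ("mosaic_switch_rate", "genotype_error_rate", "sex_mismatch_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        mix = np.array(list(self.aneuploidy_mix.values()), dtype=float)
        if (mix < 0).any():
            raise ConfigurationError("aneuploidy_mix proportions must be non-negative")
        if len(mix) and abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigurationError("aneuploidy_mix must sum to 1")
        unknown = set(self.aneuploidy_mix) - set(KARYOTYPE_CENTERS)
        if unknown:
            raise ConfigurationError(f"unknown karyotypes in aneuploidy_mix: {unknown}")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def _mosaic_haplotypes(source: np.ndarray, n_out: int, switch_rate: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_out`` haplotypes, each a mosaic copy of rows of ``source``.

    The copied source row changes at each site with probability
    ``switch_rate``; a new source is drawn uniformly at each switch.
    """
    n_src, n_sites = source.shape
    switches = rng.random((n_out, n_sites)) < switch_rate
    switches[:, 0] = True
    segment = np.cumsum(switches, axis=1) - 1
    n_seg = int(segment.max()) + 1
    seg_source = rng.integers(0, n_src, size=(n_out, n_seg))
    src_idx = np.take_along_axis(seg_source, segment, axis=1)
    return source[src_idx, np.arange(n_sites)[None, :]]


def sim_reference_panel(config: SimConfig) -> ReferencePanel:
    """Generate a phased reference panel by founder-mosaic copying."""
    if config.n_founders < 2 or config.n_sites < 2:
        raise ConfigurationError("need at least 2 founders and 2 sites")
    if config.n_haplotypes < 1:
        raise ConfigurationError("n_haplotypes must be positive")
    rng = config.rng(salt=1)
    a, b = config.allele_freq_shape
    freqs = rng.beta(a, b, size=config.n_sites)
    founders = (rng.random((config.n_founders, config.n_sites)) < freqs).astype(np.uint8)
    haps = _mosaic_haplotypes(founders, config.n_haplotypes,
                              config.mosaic_switch_rate, rng)
    positions = (np.arange(config.n_sites) + 1) * config.position_spacing
    return ReferencePanel(haps, positions)


def _assign_batches(n_samples: int, batch_spec: list) -> pd.DataFrame:
    if not batch_spec:
        batch_spec = [BatchSpec("B1", ["P1", "P2"], "A")]
    n_batches = len(batch_spec)
    bounds = np.linspace(0, n_samples, n_batches + 1).astype(int)
    batch, plate, array = [], [], []
    for k, spec in enumerate(batch_spec):
        n_in = bounds[k + 1] - bounds[k]
        batch += [spec.batch] * n_in
        plate += [spec.plates[i % len(spec.plates)] for i in range(n_in)]
        array += [spec.array] * n_in
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n_samples)],
        "batch": batch, "plate": plate, "array": array,
        "reported_sex": "", "inferred_sex": "",
    })


def _inject_errors(calls: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return calls
    mask = (rng.random(calls.shape) < rate) & (calls >= 0)
    # symmetric error: replace by one of the two other genotype values
    shift = rng.integers(1, 3, size=calls.shape)
    calls = calls.copy()
    calls[mask] = (calls[mask] + shift[mask]) % 3
    return calls


def _apply_artifacts(calls: np.ndarray, samples: pd.DataFrame, batch_spec: list,
                     rng: np.random.Generator) -> list:
    injected = []
    for spec in batch_spec:
        for art in spec.artifacts:
            rows = np.flatnonzero((samples["batch"] == art.batch).to_numpy())
            for j in art.marker_indices:
                if art.kind == "set_missing":
                    hit = rows[rng.random(len(rows)) < art.fraction]
                    calls[hit, j] = MISSING
                else:
                    target = 0 if art.kind == "het_to_homref" else 2
                    hets = rows[calls[rows, j] == 1]
                    hit = hets[rng.random(len(hets)) < art.fraction]
                    calls[hit, j] = target
                injected.append((art.batch, j, art.kind))
    return injected


def sim_cohort(panel: ReferencePanel, n_samples: int,
               config: SimConfig) -> tuple[CohortGenotypes, TruthSet]:
    """Draw a genotyped cohort from a panel by the founder-mosaic process."""
    if panel.n_haplotypes == 0 or panel.n_sites == 0:
        raise ConfigurationError("panel is empty")
    if n_samples <= 0:
        raise ConfigurationError("n_samples must be positive")
    rng = config.rng(salt=2)
    haps = _mosaic_haplotypes(panel.haplotypes, 2 * n_samples,
                              config.mosaic_switch_rate, rng)
    haps = haps.reshape(n_samples, 2, panel.n_sites)
    truth_calls = haps.sum(axis=1).astype(np.int8)
    calls = _inject_errors(truth_calls, config.genotype_error_rate, rng)
    samples = _assign_batches(n_samples, config.batch_spec)
    artifacts = _apply_artifacts(calls, samples, config.batch_spec, rng)
    markers = pd.DataFrame({
        "id": panel.ids, "chrom": panel.chrom, "pos": panel.positions,
        "ref": panel.ref, "alt": panel.alt,
    })
    cohort = CohortGenotypes(calls, markers, samples)
    truth = TruthSet(haplotypes=haps, artifact_markers=artifacts)
    return cohort, truth


# ---------------------------------------------------------------------------
# pedigree cohorts
# ---------------------------------------------------------------------------

#: template -> (expected kinship of the focal pair, expected IBS0 ~ 0 flag)
TEMPLATE_KINSHIP = {
    "duplicate": 0.5,
    "parent-offspring": 0.25,
    "full-sib": 0.25,
    "half-sib": 0.125,
    "grandparent": 0.125,
    "avuncular": 0.125,
    "first-cousin": 0.0625,
    "unrelated": 0.0,
}


def _child_of(father: np.ndarray, mother: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Gene-drop one child: per-site independent transmission from each parent.

    Transmissions are independent across sites (no within-gamete linkage);
    this preserves single-locus kinship and IBS expectations, which is all
    the relatedness stage consumes.
    """
    n_sites = father.shape[1]
    pick_f = rng.integers(0, 2, n_sites)
    pick_m = rng.integers(0, 2, n_sites)
    return np.stack([father[pick_f, np.arange(n_sites)],
                     mother[pick_m, np.arange(n_sites)]])


def sim_pedigree_cohort(n_families: int, family_templates: list, config: SimConfig,
                        include_parents: bool = False
                        ) -> tuple[CohortGenotypes, TruthSet]:
    """Gene-dropping on explicit small pedigrees.

    Each family uses one template from :data:`TEMPLATE_KINSHIP` (cycled when
    ``n_families`` exceeds the template list).  The genotyped cohort holds
    the focal pair of each family; with ``include_parents=True`` the
    pedigree parents of focal individuals are genotyped as well (so a
    ``full-sib`` family becomes a parent–parent–child–child quartet).
    Founder haplotypes are exchangeable draws from Beta-distributed site
    frequencies (no LD — pedigree cohorts exercise kinship, not imputation).
    """
    for t in family_templates:
        if t not in TEMPLATE_KINSHIP:
            raise ConfigurationError(f"unknown family template {t!r}")
    if n_families <= 0:
        raise ConfigurationError("n_families must be positive")
    rng = config.rng(salt=3)
    a, b = config.allele_freq_shape
    freqs = rng.beta(a, b, size=config.n_sites)

    def founder():
        return (rng.random((2, config.n_sites)) < freqs).astype(np.uint8)

    sample_haps, rows, parents, kinship = [], [], {}, {}

    def add(sample_id, haps, sex, age, father=None, mother=None):
        idx = len(sample_haps)
        sample_haps.append(haps)
        rows.append({"sample_id": sample_id, "batch": "B1", "plate": "P1",
                     "array": "A", "reported_sex": sex, "inferred_sex": sex,
                     "age": age})
        parents[sample_id] = (father, mother)
        return idx, sample_id

    for fam in range(n_families):
        template = family_templates[fam % len(family_templates)]
        tag = f"F{fam}"
        child_sex = "M" if rng.random() < 0.5 else "F"
        child_age = 40 + int(rng.integers(0, 15))
        parent_age = child_age + 25 + int(rng.integers(0, 10))
        if template == "duplicate":
            h = founder()
            _, s1 = add(f"{tag}_a", h, child_sex, child_age)
            _, s2 = add(f"{tag}_b", h.copy(), child_sex, child_age)
        elif template == "parent-offspring":
            pa, ma = founder(), founder()
            child = _child_of(pa, ma, rng)
            _, s1 = add(f"{tag}_p", pa, "M", parent_age)
            _, s2 = add(f"{tag}_c", child, child_sex, child_age,
                        father=f"{tag}_p")
        elif template == "full-sib":
            pa, ma = founder(), founder()
            c1, c2 = _child_of(pa, ma, rng), _child_of(pa, ma, rng)
            if include_parents:
                add(f"{tag}_f", pa, "M", parent_age, None, None)
                add(f"{tag}_m", ma, "F", parent_age, None, None)
                fa, mo = f"{tag}_f", f"{tag}_m"
            else:
                fa = mo = None
            _, s1 = add(f"{tag}_a", c1, "M", child_age, fa, mo)
            _, s2 = add(f"{tag}_b", c2, "F", child_age + 2, fa, mo)
            if include_parents:
                kinship[frozenset((f"{tag}_f", f"{tag}_a"))] = 0.25
                kinship[frozenset((f"{tag}_f", f"{tag}_b"))] = 0.25
                kinship[frozenset((f"{tag}_m", f"{tag}_a"))] = 0.25
                kinship[frozenset((f"{tag}_m", f"{tag}_b"))] = 0.25
                parents[f"{tag}_a"] = (f"{tag}_f", f"{tag}_m")
                parents[f"{tag}_b"] = (f"{tag}_f", f"{tag}_m")
        elif template == "half-sib":
            shared, m1, m2 = founder(), founder(), founder()
            _, s1 = add(f"{tag}_a", _child_of(shared, m1, rng), "M", child_age)
            _, s2 = add(f"{tag}_b", _child_of(shared, m2, rng), "F", child_age)
        elif template == "grandparent":
            g, gm, mate = founder(), founder(), founder()
            mid = _child_of(g, gm, rng)
            child = _child_of(mid, mate, rng)
            _, s1 = add(f"{tag}_g", g, "M", parent_age + 25)
            _, s2 = add(f"{tag}_c", child, child_sex, child_age)
        elif template == "avuncular":
            gf, gm, mate = founder(), founder(), founder()
            sib1, sib2 = _child_of(gf, gm, rng), _child_of(gf, gm, rng)
            nephew = _child_of(sib2, mate, rng)
            _, s1 = add(f"{tag}_u", sib1, "M", parent_age)
            _, s2 = add(f"{tag}_n", nephew, child_sex, child_age)
        elif template == "first-cousin":
            gf, gm, mate1, mate2 = founder(), founder(), founder(), founder()
            sib1, sib2 = _child_of(gf, gm, rng), _child_of(gf, gm, rng)
            c1 = _child_of(sib1, mate1, rng)
            c2 = _child_of(sib2, mate2, rng)
            _, s1 = add(f"{tag}_a", c1, "M", child_age)
            _, s2 = add(f"{tag}_b", c2, "F", child_age)
        else:  # unrelated
            _, s1 = add(f"{tag}_a", founder(), "M", child_age)
            _, s2 = add(f"{tag}_b", founder(), "F", child_age)
        kinship[frozenset((s1, s2))] = TEMPLATE_KINSHIP[template]

    haps = np.stack(sample_haps)
    truth_calls = haps.sum(axis=1).astype(np.int8)
    calls = _inject_errors(truth_calls, config.genotype_error_rate, rng)
    samples = pd.DataFrame(rows)
    markers = pd.DataFrame({
        "id": [f"m{i}" for i in range(config.n_sites)],
        "chrom": "1", "pos": (np.arange(config.n_sites) + 1) * config.position_spacing,
        "ref": "A", "alt": "G",
    })
    cohort = CohortGenotypes(calls, markers, samples)
    truth = TruthSet(haplotypes=haps, parents=parents, kinship=kinship)
    return cohort, truth


# ---------------------------------------------------------------------------
# intensity clusters and phenotypes
# ---------------------------------------------------------------------------

def sim_intensity_clusters(n_samples: int, aneuploidy_mix: dict | None,
                           config: SimConfig) -> pd.DataFrame:
    """Simulate per-sample mean X/Y log2-ratio intensity summaries.

    One Gaussian cluster per karyotype at :data:`KARYOTYPE_CENTERS`, with
    isotropic standard deviation ``config.l2r_sd``.  Reported sex equals the
    karyotype-implied sex except for ``config.sex_mismatch_fraction`` of
    samples, whose reported sex is flipped.
    """
    mix = aneuploidy_mix if aneuploidy_mix is not None else config.aneuploidy_mix
    labels = list(mix)
    probs = np.array([mix[k] for k in labels], dtype=float)
    if (probs < 0).any():
        raise ConfigurationError("aneuploidy mix proportions must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigurationError("aneuploidy mix must sum to 1")
    rng = config.rng(salt=4)
    kary = rng.choice(labels, size=n_samples, p=probs)
    centers = np.array([KARYOTYPE_CENTERS[k] for k in kary])
    xy = centers + rng.normal(0.0, config.l2r_sd, size=(n_samples, 2))
    implied = np.array([KARYOTYPE_SEX[k] for k in kary])
    reported = implied.copy()
    flip = rng.random(n_samples) < config.sex_mismatch_fraction
    reported[flip] = np.where(implied[flip] == "M", "F", "M")
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n_samples)],
        "mean_l2r_x": xy[:, 0], "mean_l2r_y": xy[:, 1],
        "true_karyotype": kary, "reported_sex": reported,
    })


@dataclass
class CovariateSpec:
    """Effects of the standard association covariates on the phenotype."""

    sex_effect: float = 0.0
    age_effect: float = 0.0
    array_effect: float = 0.0
    pc_effects: tuple = ()
    pc_scores: np.ndarray | None = None


def sim_phenotypes(cohort: CohortGenotypes, n_causal: int, h2: float,
                   covariate_spec: CovariateSpec | None = None,
                   seed: int = 0) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate an additive polygenic quantitative phenotype.

    ``h2`` is the fraction of (genetic + noise) variance that is genetic;
    covariate effects are added on top of that.  Returns the
    phenotype/covariate table and a truth set carrying the causal effects.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ConfigurationError("h2 must be in [0, 1]")
    if n_causal > cohort.n_markers:
        raise ConfigurationError("n_causal exceeds marker count")
    spec = covariate_spec or CovariateSpec()
    rng = np.random.default_rng((seed, 5))
    n = cohort.n_samples
    dosage = np.where(cohort.calls >= 0, cohort.calls, 0).astype(float)

    g = np.zeros(n)
    effects = {}
    if h2 > 0 and n_causal > 0:
        causal = rng.choice(cohort.n_markers, size=n_causal, replace=False)
        beta = rng.normal(0.0, 1.0, size=n_causal)
        g = dosage[:, causal] @ beta
        sd = g.std()
        if sd > 0:
            g = g / sd * np.sqrt(h2)
        beta_scaled = beta / sd * np.sqrt(h2) if sd > 0 else beta * 0
        effects = dict(zip(causal.tolist(), beta_scaled.tolist()))
    noise = rng.normal(0.0, np.sqrt(max(1.0 - h2, 0.0)), size=n)

    sex = cohort.samples.get("inferred_sex", pd.Series([""] * n))
    sex_num = (np.asarray(sex) == "M").astype(float)
    if "age" in cohort.samples.columns:
        age = cohort.samples["age"].to_numpy(dtype=float)
    else:
        age = rng.integers(40, 70, size=n).astype(float)
    array_num = (cohort.samples["array"].to_numpy() == "B").astype(float) \
        if "array" in cohort.samples.columns else np.zeros(n)

    y = g + noise
    y = y + spec.sex_effect * sex_num + spec.age_effect * (age - age.mean())
    y = y + spec.array_effect * array_num
    table = pd.DataFrame({
        "sample_id": cohort.samples["sample_id"],
        "phenotype": y, "sex": sex_num, "age": age, "array": array_num,
    })
    if spec.pc_scores is not None and len(spec.pc_effects):
        k = len(spec.pc_effects)
        table["phenotype"] += spec.pc_scores[:, :k] @ np.asarray(spec.pc_effects)
        for i in range(spec.pc_scores.shape[1]):
            table[f"pc{i + 1}"] = spec.pc_scores[:, i]
    truth = TruthSet(causal_effects=effects)
    return table, truth
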