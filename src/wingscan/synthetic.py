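"""Synthetic GBS SNP matrices and morphometric tables with known ground truth.

The genotype generator emulates the post-filter SNP matrix of a sympatric
wing-dimorphic stonefly sample: a panmictic background (one shared allele
frequency per neutral locus for both morphotype groups) with a small planted
set of morph-associated loci carrying large allele-frequency differences —
the "islands of divergence" signal the downstream scans are built to detect.
Defaults mirror the study scale: 34 macropterous + 62 micropterous
individuals and 6,843 biallelic SNPs that already passed a call-rate ≥ 0.5
and MAF ≥ 0.05 filter.

The morphometric generator emits forewing/body measurements for the two wing
morphs with a shared allometric body-size model and sex dimorphism (females
larger), sampled across the study's three altitude zones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import MISSING, GenotypeMatrix

GROUP_MACRO = "macropterous"
GROUP_MICRO = "micropterous"


@dataclass
class SimParams:
    """Parameters of the genotype simulator.

    ``background_fst`` > 0 adds residual drift between the two groups at
    neutral loci via Balding–Nichols beta sampling of per-group frequencies
    around the ancestral value; the default 0 encodes the panmictic
    background the study design assumes.
    """

    n_group1: int = 34
    n_group2: int = 62
    n_loci: int = 6843
    n_assoc: int = 3
    p_assoc_g1: float = 0.05
    p_assoc_g2: float = 0.95
    background_fst: float = 0.0
    maf_low: float = 0.05
    maf_high: float = 0.95
    missing_rate: float = 0.1
    snps_per_tag: int = 1
    seed: int | None = None

    def validate(self) -> None:
        if self.n_assoc > self.n_loci:
            raise ValueError("n_assoc cannot exceed n_loci")
        if self.n_group1 < 1 or self.n_group2 < 1 or self.n_loci < 1:
            raise ValueError("group sizes and locus count must be positive")
        for name in ("p_assoc_g1", "p_assoc_g2", "maf_low", "maf_high",
                     "missing_rate", "background_fst"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        if self.maf_low > self.maf_high:
            raise ValueError("maf_low must not exceed maf_high")
        if self.snps_per_tag not in (1, 2):
            raise ValueError("snps_per_tag must be 1 or 2")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated matrix."""

    assoc_locus_ids: list[str]
    freqs: pd.DataFrame  # locus_id, group1_freq, group2_freq, is_assoc

    def to_tsv(self, path: str | Path) -> None:
        self.freqs.to_csv(path, sep="\t", index=False)


def simulate_genotypes(params: SimParams) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a diploid SNP matrix with planted morph-associated loci.

    Neutral loci share one ancestral frequency (uniform on
    ``[maf_low, maf_high]``) across both groups; planted loci use the
    group-specific frequencies.  Each genotype is binomial(2, p_group) and is
    independently set missing with ``missing_rate`` — missingness carries no
    information about genotype or group.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    L, n1, n2 = params.n_loci, params.n_group1, params.n_group2

    anc = rng.uniform(params.maf_low, params.maf_high, size=L)
    if params.background_fst > 0:
        f = params.background_fst
        shape = (1.0 - f) / f
        p1 = rng.beta(anc * shape, (1.0 - anc) * shape)
        p2 = rng.beta(anc * shape, (1.0 - anc) * shape)
        # guard degenerate beta draws so every locus stays polymorphic in expectation
        p1 = np.clip(p1, 1e-6, 1.0 - 1e-6)
        p2 = np.clip(p2, 1e-6, 1.0 - 1e-6)
    else:
        p1 = anc.copy()
        p2 = anc.copy()

    assoc_idx = np.sort(rng.choice(L, size=params.n_assoc, replace=False))
    p1[assoc_idx] = params.p_assoc_g1
    p2[assoc_idx] = params.p_assoc_g2

    g1 = rng.binomial(2, p1, size=(n1, L))
    g2 = rng.binomial(2, p2, size=(n2, L))
    calls = np.vstack([g1, g2]).astype(np.int8)
    if params.missing_rate > 0:
        miss = rng.random(calls.shape) < params.missing_rate
        calls[miss] = MISSING

    if params.snps_per_tag == 1:
        positions = rng.integers(1, 70, size=L)
        locus_ids = [f"{1000 + i}_{positions[i]}" for i in range(L)]
    else:
        # two SNPs per tag (disjoint position ranges keep ids unique), to
        # exercise the one-SNP-per-tag filter; locus count stays n_loci
        locus_ids = []
        for i in range(L):
            tag = 1000 + i // 2
            pos = rng.integers(1, 35) if i % 2 == 0 else rng.integers(35, 70)
            locus_ids.append(f"{tag}_{pos}")

    individual_ids = [f"M{i + 1:03d}" for i in range(n1)] + [
        f"V{i + 1:03d}" for i in range(n2)
    ]
    labels = [GROUP_MACRO] * n1 + [GROUP_MICRO] * n2
    gm = GenotypeMatrix(individual_ids, locus_ids, calls, labels)

    is_assoc = np.zeros(L, dtype=bool)
    is_assoc[assoc_idx] = True
    truth = SimTruth(
        assoc_locus_ids=[locus_ids[i] for i in assoc_idx],
        freqs=pd.DataFrame(
            {
                "locus_id": locus_ids,
                "group1_freq": p1,
                "group2_freq": p2,
                "is_assoc": is_assoc,
            }
        ),
    )
    return gm, truth


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------


@dataclass
class MorphParams:
    """Parameters of the morphometric generator.

    Ratio distributions are truncated normals with class-specific support:
    vestigial wings are a small but positive fraction of body length, full
    wings at least body-sized.  The bounded support reproduces the complete
    separation of the two observed ratio distributions while keeping the
    published class means/dispersions.  Set ``dispersion_is_se=True`` to
    reinterpret the dispersion values as standard errors of the class means
    (per-individual SD is then ``dispersion × sqrt(n_class)``).
    """

    ratio_mean_macro: float = 1.06
    ratio_disp_macro: float = 0.15
    ratio_mean_micro: float = 0.26
    ratio_disp_micro: float = 0.28
    ratio_bounds_macro: tuple[float, float] = (0.70, 1.50)
    ratio_bounds_micro: tuple[float, float] = (0.02, 0.55)
    dispersion_is_se: bool = False
    body_mean_female: float = 10.5
    body_mean_male: float = 8.5
    body_sd: float = 0.9
    forewing_noise_sd: float = 0.12
    prop_female: float = 0.5
    altitudes_m: tuple[int, ...] = (90, 130, 200)

    def validate(self) -> None:
        for name in ("ratio_disp_macro", "ratio_disp_micro", "body_sd",
                     "forewing_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.body_sd == 0 and self.forewing_noise_sd == 0:
            pass  # noise-free generation is allowed (degenerate tests)
        if not 0 <= self.prop_female <= 1:
            raise ValueError("prop_female must be a proportion")


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_morphometrics(
    n1: int,
    n2: int,
    params: MorphParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a morphometric table for ``n1`` macropterous and ``n2``
    micropterous individuals.

    Columns: ``id, sex, altitude_m, body_mm, forewing_mm, true_class``.
    Forewing length is ratio × body length plus measurement noise; sampling
    altitude is drawn uniformly from the three survey zones and is
    independent of morph by construction.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both class sizes must be at least 1")
    params = params or MorphParams()
    params.validate()
    rng = np.random.default_rng(seed)

    rows = []
    specs = [
        (GROUP_MACRO, n1, params.ratio_mean_macro, params.ratio_disp_macro,
         params.ratio_bounds_macro, "W"),
        (GROUP_MICRO, n2, params.ratio_mean_micro, params.ratio_disp_micro,
         params.ratio_bounds_micro, "V"),
    ]
    for cls, n, mu, disp, (lo, hi), prefix in specs:
        sd = disp * np.sqrt(n) if params.dispersion_is_se else disp
        sex = np.where(rng.random(n) < params.prop_female, "F", "M")
        body_mu = np.where(sex == "F", params.body_mean_female, params.body_mean_male)
        body = body_mu + params.body_sd * rng.standard_normal(n)
        body = np.maximum(body, 1.0)
        ratio = _truncnorm(rng, mu, sd, lo, hi, n)
        wing = ratio * body + params.forewing_noise_sd * rng.standard_normal(n)
        wing = np.maximum(wing, 0.01)
        alt = rng.choice(params.altitudes_m, size=n)
        for i in range(n):
            rows.append(
                (f"{prefix}{i + 1:03d}", sex[i], int(alt[i]),
                 float(body[i]), float(wing[i]), cls)
            )
    return pd.DataFrame(
        rows, columns=["id", "sex", "altitude_m", "body_mm", "forewing_mm", "true_class"]
    )
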