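"""Synthetic data generators with known ground truth.

Three layers mirror the real inputs of the repositioning pipeline:

* a GWAS layer — block-AR(1) LD, per-gene sparse eQTL weights, and GWAS
  z-scores drawn from MVN(V W b, V) so that causal genes carry real signal
  through the TWAS formula and null genes are exactly calibrated;
* a perturbagen library — profiles that reverse (negative multiple of the
  standardized disease signature plus noise), mimic (positive multiple) or
  ignore (pure noise) a given disease signature;
* longitudinal claims — enrollment/diagnosis/prescription tables whose
  acute-medication counts follow the log-linear person-period model
  ln(Y+1) = b0 + a*t + sum b_k x_k + g_i + ln(time) + e, with planted
  eligibility-rule violators so cohort filters are exercised.

Every generator is bit-reproducible given its arguments and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .claims import ClaimsTables, DAYS_PER_YEAR
from .imputation import (
    EQTLWeightSet,
    GWASSummary,
    GeneAnnotation,
    LDReference,
    TissueSignature,
)
from .screen import PerturbagenLibrary

logger = logging.getLogger(__name__)

#: Nervous-system tissue labels used when generating multi-tissue panels.
NERVOUS_TISSUE_NAMES = (
    "brain_cortex", "brain_cerebellum", "brain_hippocampus",
    "brain_hypothalamus", "spinal_cord_cervical",
)
WHOLE_BLOOD = "whole_blood"


# ---------------------------------------------------------------------------
# Ground-truth records
# ---------------------------------------------------------------------------

@dataclass
class GenomeTruth:
    """Planted causal structure of the simulated GWAS layer."""

    causal_genes: set[str]
    effect_sizes: dict[str, float]
    tissues: list[str]
    variant_to_gene: dict[str, str]
    causal_tissue: str

    def __post_init__(self) -> None:
        universe = set(self.variant_to_gene.values())
        if not self.causal_genes <= universe:
            raise ValueError("causal genes must lie in the generated gene universe")
        if not all(np.isfinite(list(self.effect_sizes.values()) or [0.0])):
            raise ValueError("effect sizes must be finite")


@dataclass
class PerturbagenTruth:
    """Which library signatures were planted as reversers or mimickers."""

    reverser_ids: set[str]
    mimicker_ids: set[str]
    strength: float

    def __post_init__(self) -> None:
        if self.reverser_ids & self.mimicker_ids:
            raise ValueError("a signature cannot be both reverser and mimicker")
        if not 0 < self.strength <= 1:
            raise ValueError("planted reversal strength must be in (0, 1]")


@dataclass
class ClaimsTruth:
    """Generative values of the person-period count model."""

    beta0: float
    alphas: dict[str, float]          # drug -> true log effect a
    betas: dict[str, float] = field(default_factory=dict)  # covariate code -> b_k
    tau: float = 0.5                  # random-intercept SD
    sigma: float = 0.6                # residual SD

    def __post_init__(self) -> None:
        if self.tau < 0 or self.sigma < 0:
            raise ValueError("variance components must be non-negative")
        for d, a in self.alphas.items():
            if not np.isfinite(a):
                raise ValueError(f"alpha for drug {d!r} must be finite (exp(a) > 0)")


@dataclass
class EligibilityNoise:
    """Fractions of patients planted to violate each cohort rule."""

    frac_cardio_history: float = 0.0   # pre-index I21 diagnosis (rule 4)
    frac_short_enrollment: float = 0.0  # < 180 d pre-index enrollment (rule 3)
    frac_zero_followup: float = 0.0    # enrollment ends on index date (rule 5)


# ---------------------------------------------------------------------------
# GWAS layer
# ---------------------------------------------------------------------------

def _ar1_block(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def block_ar1_ld(n_variants: int, block_size: int, rho: float,
                 variant_ids: list[str] | None = None) -> LDReference:
    """Block-diagonal AR(1) LD: within-block correlation rho^|i-j|.

    AR(1) blocks with |rho| < 1 are positive definite, so the whole matrix
    is too; this gives the generator a closed-form, always-valid LD model.
    """
    if block_size < 1:
        raise ValueError("ld_block_size must be >= 1")
    if not abs(rho) < 1:
        raise ValueError(
            f"AR(1) block with block_size={block_size}, rho={rho} is not "
            "positive definite (need |rho| < 1)"
        )
    mat = np.zeros((n_variants, n_variants))
    for start in range(0, n_variants, block_size):
        size = min(block_size, n_variants - start)
        mat[start:start + size, start:start + size] = _ar1_block(size, rho)
    ids = variant_ids or [f"rs{i + 1:06d}" for i in range(n_variants)]
    return LDReference(ids, mat)


def simulate_gwas_layer(
    n_variants: int,
    n_genes: int,
    n_tissues: int,
    causal_fraction: float,
    ld_block_size: int,
    ld_rho: float,
    seed: int,
    effect_size_range: tuple[float, float] = (2.0, 4.0),
    panel_fraction: float = 0.2,
) -> tuple[GWASSummary, LDReference, dict[str, EQTLWeightSet], GeneAnnotation, GenomeTruth]:
    """Simulate GWAS z-scores, LD, eQTL weights and gene annotation.

    Variants are split into contiguous per-gene chunks; each gene's weight
    vector is drawn over its assigned variants and normalized so that
    wT V w = 1 with its largest-magnitude entry positive (a one-variant
    gene therefore has weight exactly +1).  Causal genes act through the
    first nervous-system tissue's weights: z ~ MVN(V W b, V), where b is
    nonzero only for causal genes.  Tissue gene panels are random subsets,
    with causal genes added to the causal tissue's panel so enrichment has
    signal to find.
    """
    if not 0 <= causal_fraction < 1:
        raise ValueError("causal_fraction must be in [0, 1)")
    if n_genes < 1 or n_variants < n_genes:
        raise ValueError("need n_variants >= n_genes >= 1")
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues (whole blood + one nervous)")
    rng = np.random.default_rng(seed)

    ld = block_ar1_ld(n_variants, ld_block_size, ld_rho)
    variant_ids = np.array(ld.variant_ids)
    genes = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    chunks = np.array_split(np.arange(n_variants), n_genes)
    variant_to_gene = {}
    gene_variants: dict[str, list[str]] = {}
    for g, idx in zip(genes, chunks):
        gene_variants[g] = [variant_ids[i] for i in idx]
        for i in idx:
            variant_to_gene[variant_ids[i]] = g

    n_nervous = min(len(NERVOUS_TISSUE_NAMES), n_tissues - 1)
    tissues = [WHOLE_BLOOD] + list(NERVOUS_TISSUE_NAMES[:n_nervous])
    tissues += [f"tissue_{i + 1:02d}" for i in range(n_tissues - len(tissues))]
    causal_tissue = tissues[1]

    # Per-tissue normalized weight vectors over each gene's assigned variants.
    weight_sets: dict[str, EQTLWeightSet] = {}
    for t in tissues:
        wmap: dict[str, dict[str, float]] = {}
        for g, idx in zip(genes, chunks):
            w = rng.normal(size=len(idx))
            v_sub = ld.matrix[np.ix_(idx, idx)]
            norm = np.sqrt(w @ v_sub @ w)
            if norm <= 0:
                w = np.ones(len(idx))
                norm = np.sqrt(w @ v_sub @ w)
            w = w / norm
            if w[np.argmax(np.abs(w))] < 0:
                w = -w
            wmap[g] = dict(zip((variant_ids[i] for i in idx), w))
        weight_sets[t] = EQTLWeightSet(t, wmap)

    n_causal = int(round(causal_fraction * n_genes))
    causal = sorted(rng.choice(genes, size=n_causal, replace=False).tolist())
    signs = rng.choice([-1.0, 1.0], size=n_causal)
    mags = rng.uniform(*effect_size_range, size=n_causal)
    effects = {g: float(s * m) for g, s, m in zip(causal, signs, mags)}

    # Mean of z is V W b with W from the causal tissue; draw block by block.
    b_snp = np.zeros(n_variants)
    wcaus = weight_sets[causal_tissue].weights
    pos = {v: i for i, v in enumerate(variant_ids)}
    for g, b in effects.items():
        for v, w in wcaus[g].items():
            b_snp[pos[v]] += w * b
    z = np.empty(n_variants)
    for start in range(0, n_variants, ld_block_size):
        size = min(ld_block_size, n_variants - start)
        v_blk = ld.matrix[start:start + size, start:start + size]
        mean = v_blk @ b_snp[start:start + size]
        chol = np.linalg.cholesky(v_blk)
        z[start:start + size] = mean + chol @ rng.normal(size=size)

    gwas = GWASSummary(pd.DataFrame({
        "variant_id": variant_ids,
        "effect_allele": "A",
        "other_allele": "G",
        "z": z,
    }))

    panels: dict[str, set[str]] = {}
    for t in tissues:
        k = max(1, int(round(panel_fraction * n_genes)))
        panels[t] = set(rng.choice(genes, size=k, replace=False).tolist())
    panels[causal_tissue] |= set(causal)
    annotation = GeneAnnotation(
        gene_variants=gene_variants,
        tissue_panels=panels,
        nervous_tissues=set(NERVOUS_TISSUE_NAMES[:n_nervous]),
        whole_blood=WHOLE_BLOOD,
    )
    truth = GenomeTruth(set(causal), effects, tissues, variant_to_gene, causal_tissue)
    return gwas, ld, weight_sets, annotation, truth


# ---------------------------------------------------------------------------
# Perturbagen library
# ---------------------------------------------------------------------------

def simulate_perturbagen_library(
    signature: TissueSignature,
    n_signatures: int,
    n_reversers: int,
    n_mimickers: int,
    strength: float,
    noise_sd: float,
    seed: int,
) -> tuple[PerturbagenLibrary, PerturbagenTruth]:
    """Plant reversers and mimickers of a disease signature in a noise library.

    Reversers are -strength * standardized(signature) + noise_sd * N(0,1);
    mimickers flip the sign; the remaining profiles are standard-normal
    noise.  One signature per perturbagen; the gene universe matches the
    disease signature's genes.
    """
    if len(signature) == 0:
        raise ValueError("disease signature is empty")
    if n_reversers + n_mimickers > n_signatures:
        raise ValueError("planted profiles exceed library size")
    if not 0 < strength <= 1:
        raise ValueError("strength must be in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    z = signature.z.to_numpy()
    std = (z - z.mean()) / z.std()
    g = len(z)
    cols = np.empty((g, n_signatures))
    for j in range(n_signatures):
        if j < n_reversers:
            cols[:, j] = -strength * std + noise_sd * rng.normal(size=g)
        elif j < n_reversers + n_mimickers:
            cols[:, j] = strength * std + noise_sd * rng.normal(size=g)
        else:
            cols[:, j] = rng.normal(size=g)
    sids = [f"sig_{j + 1:05d}" for j in range(n_signatures)]
    names = []
    for j in range(n_signatures):
        if j < n_reversers:
            names.append(f"reverser_{j + 1:03d}")
        elif j < n_reversers + n_mimickers:
            names.append(f"mimicker_{j - n_reversers + 1:03d}")
        else:
            names.append(f"compound_{j - n_reversers - n_mimickers + 1:05d}")
    matrix = pd.DataFrame(cols, index=signature.z.index, columns=sids)
    meta = pd.DataFrame({
        "signature_id": sids,
        "perturbagen": names,
        "cell_line": "cell_a",
    })
    lib = PerturbagenLibrary(matrix, meta)
    truth = PerturbagenTruth(
        reverser_ids=set(names[:n_reversers]),
        mimicker_ids=set(names[n_reversers:n_reversers + n_mimickers]),
        strength=strength,
    )
    return lib, truth


# ---------------------------------------------------------------------------
# Claims layer
# ---------------------------------------------------------------------------

DEFAULT_ACUTE_CODES = ("triptan", "ergotamine", "ditan")
#: Rule-2 qualifying prophylactic given to every simulated patient at index;
#: deliberately not an acute (outcome) code so counts stay on-model.
PROPHYLACTIC_CODE = "migraine_prophylactic"


def simulate_claims(
    n_patients: int,
    truth: ClaimsTruth,
    n_windows_mean: float = 3.0,
    acute_drug_codes: tuple[str, ...] = DEFAULT_ACUTE_CODES,
    exposure_codes: dict[str, tuple[str, ...]] | None = None,
    eligibility_noise: EligibilityNoise | None = None,
    seed: int = 0,
    window_days: int = 365,
    user_fraction: float = 0.5,
    covariate_prob: float = 0.3,
    index_start: date = date(2018, 9, 1),
    index_span_days: int = 720,
) -> tuple[ClaimsTables, ClaimsTruth]:
    """Simulate raw claims tables realizing the log-linear count model.

    Each patient gets an index migraine diagnosis, an enrollment span of
    exactly their drawn number of windows, and per-window acute-medication
    counts Y = max(0, round(exp(L) - 1)) for the latent
    L = b0 + sum_d a_d t_d + sum_k b_k x_k + g_i + ln(time) + e.
    Drug users start exposure at a uniformly chosen window and remain
    exposed; covariates are window-level Bernoulli indicators realized as
    prescription records, as are exposures.  A configurable fraction of
    patients is planted to violate each eligibility rule.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    exposure_codes = exposure_codes or {d: (d,) for d in truth.alphas}
    noise = eligibility_noise or EligibilityNoise()
    flat_exposure = {c for codes in exposure_codes.values() for c in codes}
    overlap = flat_exposure & set(acute_drug_codes)
    if overlap:
        raise ValueError(
            f"exposure codes overlap acute outcome codes: {sorted(overlap)} "
            "(outcome/exposure confounding by construction)"
        )
    for d in truth.alphas:
        if d not in exposure_codes:
            raise ValueError(f"no exposure codes supplied for drug {d!r}")
    rng = np.random.default_rng(seed)

    drugs = sorted(truth.alphas)
    cov_codes = sorted(truth.betas)
    time_full = window_days / DAYS_PER_YEAR
    ln_time = np.log(time_full)

    enroll_rows, dx_rows, rx_rows = [], [], []
    n_cardio = int(round(noise.frac_cardio_history * n_patients))
    n_short = int(round(noise.frac_short_enrollment * n_patients))
    n_zero = int(round(noise.frac_zero_followup * n_patients))
    violators = rng.permutation(n_patients)
    cardio_set = set(violators[:n_cardio])
    short_set = set(violators[n_cardio:n_cardio + n_short])
    zero_set = set(violators[n_cardio + n_short:n_cardio + n_short + n_zero])

    for i in range(n_patients):
        pid = f"p{i + 1:06d}"
        index = index_start + timedelta(days=int(rng.integers(0, index_span_days)))
        n_win = 1 + int(rng.poisson(max(n_windows_mean - 1.0, 0.0)))
        if i in zero_set:
            n_win = 0
        pre_days = int(rng.integers(200, 1500))
        if i in short_set:
            pre_days = int(rng.integers(10, 179))
        start = index - timedelta(days=pre_days)
        end = index + timedelta(days=n_win * window_days)
        birth_year = int(rng.integers(1955, 2005))
        sex = "F" if rng.random() < 0.7 else "M"
        enroll_rows.append((pid, start, end, birth_year, sex))
        dx_rows.append((pid, index, "G431"))
        rx_rows.append((pid, index, PROPHYLACTIC_CODE, "migraine_specific"))
        if i in cardio_set:
            dx_rows.append((pid, index - timedelta(days=50), "I219"))

        gamma = rng.normal(0.0, truth.tau)
        user = {d: rng.random() < user_fraction for d in drugs}
        start_win = {d: int(rng.integers(0, n_win)) if n_win else 0 for d in drugs}
        for j in range(n_win):
            wstart = index + timedelta(days=j * window_days)
            latent = truth.beta0 + gamma + ln_time + rng.normal(0.0, truth.sigma)
            for d in drugs:
                exposed = user[d] and j >= start_win[d]
                if exposed:
                    latent += truth.alphas[d]
                    rx_day = int(rng.integers(0, window_days))
                    code = exposure_codes[d][0]
                    rx_rows.append((pid, wstart + timedelta(days=rx_day), code,
                                    f"class_{d}"))
            for c in cov_codes:
                if rng.random() < covariate_prob:
                    latent += truth.betas[c]
                    rx_day = int(rng.integers(0, window_days))
                    rx_rows.append((pid, wstart + timedelta(days=rx_day), c,
                                    f"class_{c}"))
            y = max(0, int(np.round(np.exp(latent) - 1.0)))
            if y:
                days = rng.integers(0, window_days, size=y)
                codes = rng.choice(acute_drug_codes, size=y)
                for day, code in zip(days, codes):
                    rx_rows.append((pid, wstart + timedelta(days=int(day)),
                                    str(code), "acute_migraine"))

    enrollment = pd.DataFrame(
        enroll_rows,
        columns=["person_id", "start_date", "end_date", "birth_year", "sex"],
    )
    diagnoses = pd.DataFrame(dx_rows, columns=["person_id", "date", "icd10_code"])
    prescriptions = pd.DataFrame(
        rx_rows, columns=["person_id", "date", "drug_code", "drug_class"],
    )
    return ClaimsTables(enrollment, diagnoses, prescriptions), truth


# ---------------------------------------------------------------------------
# Truth sidecar
# ---------------------------------------------------------------------------

def truth_sidecar(truth: GenomeTruth | PerturbagenTruth | ClaimsTruth) -> pd.DataFrame:
    """Flatten a truth record into a key-value table (one row per effect)."""
    rows: list[tuple[str, str]] = []
    if isinstance(truth, GenomeTruth):
        rows.append(("causal_tissue", truth.causal_tissue))
        for g in sorted(truth.causal_genes):
            rows.append((f"effect:{g}", repr(truth.effect_sizes[g])))
    elif isinstance(truth, PerturbagenTruth):
        rows.append(("strength", repr(truth.strength)))
        for r in sorted(truth.reverser_ids):
            rows.append((f"reverser:{r}", "1"))
        for m in sorted(truth.mimicker_ids):
            rows.append((f"mimicker:{m}", "1"))
    elif isinstance(truth, ClaimsTruth):
        rows.append(("beta0", repr(truth.beta0)))
        rows.append(("tau", repr(truth.tau)))
        rows.append(("sigma", repr(truth.sigma)))
        for d, a in sorted(truth.alphas.items()):
            rows.append((f"alpha:{d}", repr(a)))
        for c, b in sorted(truth.betas.items()):
            rows.append((f"beta:{c}", repr(b)))
    else:
        raise TypeError(f"unknown truth record type: {type(truth)!r}")
    return pd.DataFrame(rows, columns=["key", "value"])
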