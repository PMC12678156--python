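"""Tissue selection and TWAS signature imputation from GWAS summary statistics.

Given per-variant GWAS z-scores ``X``, a variant correlation (LD) matrix
``V`` and per-gene eQTL weight vectors ``w``, the expression-trait
association z-score for a gene is

    Z_TWAS = wᵀX / sqrt(wᵀ V w)

which is standard normal under the null that the gene's genetically
predicted expression is unrelated to the trait.  Disease-relevant tissues
are chosen by a gene-set enrichment test on tissue-specific gene panels,
fed by a gene-level association statistic (sum of per-variant chi-squares,
moment-matched for LD).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Shrinkage weight for LD regularization V <- (1-l)V + l*I.
DEFAULT_RIDGE = 0.1
#: Genes whose regularized denominator wᵀVw falls below this are skipped.
DENOM_TOL = 1e-12
#: Gene-level association threshold defining "disease genes" for enrichment.
DISEASE_GENE_ALPHA = 0.05
#: Tissue enrichment threshold.
TISSUE_ALPHA = 0.05
#: Number of top nervous-system tissues always carried forward.
N_NERVOUS = 3


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GWASSummary:
    """Per-variant GWAS association z-scores.

    ``table`` has columns ``variant_id, effect_allele, other_allele, z``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["variant_id", "effect_allele", "other_allele", "z"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"GWAS table missing columns: {missing}")
        if self.table["variant_id"].duplicated().any():
            dup = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ValueError(f"duplicate variant_id in GWAS table: {dup!r}")
        z = pd.to_numeric(self.table["z"], errors="coerce")
        if not np.isfinite(z.to_numpy(dtype=float)).all():
            raise ValueError("GWAS z-scores must all be finite")
        self.table = self.table.assign(z=z.astype(float)).reset_index(drop=True)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    def z_series(self) -> pd.Series:
        return self.table.set_index("variant_id")["z"]


@dataclass
class LDReference:
    """Variant correlation matrix with its variant ordering."""

    variant_ids: list[str]
    matrix: np.ndarray
    _SYM_TOL = 1e-8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.variant_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"LD matrix shape {self.matrix.shape} does not match "
                f"{n} variant ids"
            )
        # chunked symmetry check to bound temporaries on large panels
        chunk = 2048
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            asym = np.abs(self.matrix[lo:hi] - self.matrix[:, lo:hi].T)
            if asym.size and asym.max() > self._SYM_TOL:
                i, j = np.unravel_index(np.argmax(asym), asym.shape)
                i += lo
                raise ValueError(
                    f"LD matrix is asymmetric at cell "
                    f"({self.variant_ids[i]}, {self.variant_ids[j]}): "
                    f"{self.matrix[i, j]:.6g} vs {self.matrix[j, i]:.6g}"
                )
        if n and np.abs(np.diag(self.matrix) - 1.0).max() > 1e-6:
            k = int(np.argmax(np.abs(np.diag(self.matrix) - 1.0)))
            raise ValueError(
                f"LD matrix diagonal is not 1 at {self.variant_ids[k]}"
            )

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0]) if len(self.variant_ids) else 0.0

    def submatrix(self, ids: list[str]) -> np.ndarray:
        pos = {v: i for i, v in enumerate(self.variant_ids)}
        idx = [pos[v] for v in ids]
        return self.matrix[np.ix_(idx, idx)]


@dataclass
class EQTLWeightSet:
    """Per-gene sparse eQTL weight vectors for one tissue.

    ``weights`` maps gene id -> {variant_id: weight}.  ``alleles`` optionally
    records the effect/other allele each weight refers to, enabling
    harmonization against GWAS allele orientation.
    """

    tissue: str
    weights: dict[str, dict[str, float]]
    alleles: pd.DataFrame | None = None  # variant_id, effect_allele, other_allele

    def __post_init__(self) -> None:
        for gene, wv in self.weights.items():
            if not wv:
                raise ValueError(f"gene {gene!r} has an empty weight vector")
            if not all(np.isfinite(list(wv.values()))):
                raise ValueError(f"gene {gene!r} has non-finite weights")

    @property
    def genes(self) -> list[str]:
        return list(self.weights)

    def variant_ids(self) -> set[str]:
        out: set[str] = set()
        for wv in self.weights.values():
            out.update(wv)
        return out


@dataclass
class GeneAnnotation:
    """Gene-to-variant assignment plus tissue gene panels.

    ``gene_variants`` drives the gene-level association test;
    ``tissue_panels`` drives tissue enrichment; ``nervous_tissues`` marks
    which tissue labels belong to the nervous system.
    """

    gene_variants: dict[str, list[str]]
    tissue_panels: dict[str, set[str]]
    nervous_tissues: set[str]
    whole_blood: str = "whole_blood"

    def __post_init__(self) -> None:
        universe = set(self.gene_variants)
        for tissue, panel in self.tissue_panels.items():
            extra = set(panel) - universe
            if extra:
                raise ValueError(
                    f"tissue panel {tissue!r} contains genes outside the "
                    f"gene universe, e.g. {sorted(extra)[:3]}"
                )

    @property
    def gene_universe(self) -> set[str]:
        return set(self.gene_variants)


@dataclass
class TissueSignature:
    """Imputed per-gene TWAS z-scores for one tissue."""

    tissue: str
    z: pd.Series  # index: gene id
    skipped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.z.index.duplicated().any():
            raise ValueError("duplicate gene ids in signature")
        if len(self.z) and not np.isfinite(self.z.to_numpy(dtype=float)).all():
            raise ValueError("signature z-scores must be finite")
        self.z = self.z.astype(float)

    @property
    def genes(self) -> list[str]:
        return self.z.index.tolist()

    def __len__(self) -> int:
        return len(self.z)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def harmonize(
    gwas: GWASSummary, ld: LDReference, weights: EQTLWeightSet
) -> tuple[GWASSummary, LDReference, EQTLWeightSet]:
    """Restrict all three inputs to a shared, allele-consistent variant set.

    Variants present in all of (GWAS, LD, weights) are kept.  Where the
    weight set records alleles and they are swapped relative to the GWAS
    orientation, the GWAS z is negated; variants whose allele pairs do not
    match either orientation are dropped (count logged).
    """
    gtab = gwas.table.set_index("variant_id")
    shared = [v for v in ld.variant_ids if v in gtab.index and v in weights.variant_ids()]
    dropped_mismatch = 0
    flipped = 0
    keep: list[str] = []
    z_sign: dict[str, float] = {}
    if weights.alleles is not None:
        wall = weights.alleles.set_index("variant_id")
    else:
        wall = None
    for v in shared:
        sign = 1.0
        if wall is not None and v in wall.index:
            ea_g, oa_g = gtab.loc[v, "effect_allele"], gtab.loc[v, "other_allele"]
            ea_w, oa_w = wall.loc[v, "effect_allele"], wall.loc[v, "other_allele"]
            if (ea_g, oa_g) == (ea_w, oa_w):
                sign = 1.0
            elif (ea_g, oa_g) == (oa_w, ea_w):
                sign = -1.0
                flipped += 1
            else:
                dropped_mismatch += 1
                continue
        keep.append(v)
        z_sign[v] = sign
    if dropped_mismatch:
        logger.warning("harmonize: dropped %d variants with mismatched allele pairs",
                       dropped_mismatch)
    if flipped:
        logger.info("harmonize: flipped z sign for %d swapped-allele variants", flipped)
    if not keep:
        raise ValueError("harmonize: no shared variants between GWAS, LD and weights")

    new_tab = gtab.loc[keep].reset_index()
    new_tab["z"] = new_tab["z"] * new_tab["variant_id"].map(z_sign)
    new_gwas = GWASSummary(new_tab)
    new_ld = LDReference(list(keep), ld.submatrix(list(keep)))
    keep_set = set(keep)
    new_w = {}
    for gene, wv in weights.weights.items():
        sub = {v: w for v, w in wv.items() if v in keep_set and w != 0.0}
        if sub:
            new_w[gene] = sub
    if not new_w:
        raise ValueError("harmonize: no gene retains a nonzero weight after harmonization")
    new_weights = EQTLWeightSet(weights.tissue, new_w, alleles=weights.alleles)
    return new_gwas, new_ld, new_weights


# ---------------------------------------------------------------------------
# Gene-level association (sum-of-chi-squares surrogate with LD moment match)
# ---------------------------------------------------------------------------

def _weighted_chi2_sf(s: float, lam: np.ndarray) -> float:
    """Upper tail of S = sum_i lam_i * chi2_1 at s, by Imhof integration.

    The moments E[S] = sum(lam) and Var[S] = 2 sum(lam^2) match the
    LD-aware statistic; when all eigenvalues coincide the tail is an exact
    scaled chi-square, otherwise Imhof's inversion formula

        P(S > s) = 1/2 + (1/pi) int_0^inf sin(theta(u)) / (u rho(u)) du

    is evaluated numerically (accurate to quadrature tolerance).
    """
    from scipy.integrate import quad

    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0 or s <= 0:
        return 1.0
    if np.allclose(lam, lam[0]):
        return float(stats.chi2.sf(s / lam[0], len(lam)))

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * s * u
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return np.sin(theta) / (u * rho)

    val, _ = quad(integrand, 0.0, np.inf, limit=400)
    return float(min(max(0.5 + val / np.pi, np.finfo(float).tiny), 1.0))


def gene_association(
    gwas: GWASSummary, ld: LDReference, annotation: GeneAnnotation
) -> pd.Series:
    """Per-gene association p-value from its variants' GWAS z-scores.

    The statistic is S = Σ z_i² over the gene's variants.  Under the null,
    z ~ MVN(0, R) for the gene's LD submatrix R, so S is a weighted sum of
    independent 1-df chi-squares with weights equal to R's eigenvalues; the
    p-value is that distribution's exact upper tail.  This is a surrogate
    for a dedicated gene-based association tool, preserving its role of
    producing LD-aware gene-level p-values.
    """
    zmap = gwas.z_series()
    pos = {v: i for i, v in enumerate(ld.variant_ids)}
    out: dict[str, float] = {}
    for gene, variants in annotation.gene_variants.items():
        vs = [v for v in variants if v in zmap.index and v in pos]
        if not vs:
            warnings.warn(f"gene {gene!r} has no harmonized variants; excluded")
            continue
        z = zmap.loc[vs].to_numpy()
        s = float(np.sum(z ** 2))
        r = ld.matrix[np.ix_([pos[v] for v in vs], [pos[v] for v in vs])]
        lam = np.linalg.eigvalsh(np.atleast_2d(r))
        out[gene] = _weighted_chi2_sf(s, lam)
    return pd.Series(out, name="p").sort_index()


# ---------------------------------------------------------------------------
# Tissue enrichment and selection
# ---------------------------------------------------------------------------

def tissue_enrichment(
    disease_genes: set[str], annotation: GeneAnnotation
) -> pd.Series:
    """One-sided Fisher exact enrichment of disease genes in tissue panels.

    For each tissue panel the 2x2 table over the gene universe is
    (disease & panel, disease & not panel, panel & not disease, neither)
    and the p-value is the upper (enrichment) tail.
    """
    if not disease_genes:
        raise ValueError("disease_genes must be nonempty")
    universe = annotation.gene_universe
    d = set(disease_genes) & universe
    out = {}
    for tissue, panel in annotation.tissue_panels.items():
        panel = set(panel)
        if not panel:
            warnings.warn(f"tissue {tissue!r} has an empty panel; p set to 1")
            out[tissue] = 1.0
            continue
        a = len(d & panel)
        b = len(d - panel)
        c = len(panel - d)
        dd = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, dd]], alternative="greater")
        out[tissue] = float(p)
    return pd.Series(out, name="p").sort_index()


def select_tissues(enrichment: pd.Series, annotation: GeneAnnotation) -> list[str]:
    """Tissues carried into signature imputation.

    Union of (i) tissues enriched at p < 0.05, (ii) the three nervous-system
    tissues with smallest p, and (iii) whole blood.  Ordered by ascending p,
    ties broken by tissue id.
    """
    if annotation.whole_blood not in annotation.tissue_panels:
        raise ValueError(
            f"whole-blood label {annotation.whole_blood!r} absent from annotation"
        )
    enr = enrichment.to_dict()
    selected = {t for t, p in enr.items() if p < TISSUE_ALPHA}
    nervous = sorted(
        (t for t in annotation.nervous_tissues if t in enr),
        key=lambda t: (enr[t], t),
    )
    if len(nervous) < N_NERVOUS:
        logger.warning(
            "only %d nervous-system tissues available (wanted %d); using all",
            len(nervous), N_NERVOUS,
        )
    selected.update(nervous[:N_NERVOUS])
    selected.add(annotation.whole_blood)
    return sorted(selected, key=lambda t: (enr.get(t, 1.0), t))


# ---------------------------------------------------------------------------
# TWAS z-score and signature imputation
# ---------------------------------------------------------------------------

def twas_zscore(
    w: np.ndarray, x: np.ndarray, v: np.ndarray, ridge: float = DEFAULT_RIDGE
) -> float:
    """TWAS z-score wᵀx / sqrt(wᵀVw) with ridge-regularized V.

    ``v`` is regularized as (1-ridge)·V + ridge·I before forming the
    denominator, which stabilizes genes whose weighted variants are in
    near-perfect LD.  The statistic is invariant to positive rescaling
    of ``w``.
    """
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    if w.ndim != 1 or not np.any(w):
        raise ValueError("weight vector must be 1-d and nonzero")
    vr = (1.0 - ridge) * v + ridge * np.eye(len(w))
    denom = float(w @ vr @ w)
    if denom <= DENOM_TOL:
        raise ValueError(
            f"degenerate TWAS denominator ({denom:.3g}) after regularization"
        )
    return float(w @ x) / np.sqrt(denom)


def impute_signature(
    tissue: str,
    weights: EQTLWeightSet,
    gwas: GWASSummary,
    ld: LDReference,
    ridge: float = DEFAULT_RIDGE,
) -> TissueSignature:
    """Impute the per-gene TWAS z-score signature for one tissue."""
    if weights.tissue != tissue:
        raise ValueError(
            f"weight set is for tissue {weights.tissue!r}, not {tissue!r}"
        )
    zmap = gwas.z_series()
    pos = {v: i for i, v in enumerate(ld.variant_ids)}
    zs: dict[str, float] = {}
    skipped: list[str] = []
    for gene, wv in weights.weights.items():
        vs = [v for v in wv if v in zmap.index and v in pos]
        if not vs:
            skipped.append(gene)
            continue
        w = np.array([wv[v] for v in vs])
        x = zmap.loc[vs].to_numpy()
        idx = [pos[v] for v in vs]
        v_sub = ld.matrix[np.ix_(idx, idx)]
        try:
            zs[gene] = twas_zscore(w, x, v_sub, ridge=ridge)
        except ValueError:
            skipped.append(gene)
    if skipped:
        logger.warning("impute_signature(%s): skipped %d genes", tissue, len(skipped))
    if not zs:
        raise ValueError(f"no genes retained for tissue {tissue!r}")
    return TissueSignature(tissue, pd.Series(zs).sort_index(), skipped_genes=skipped)


def impute_all(
    tissues: list[str],
    weight_sets: dict[str, EQTLWeightSet],
    gwas: GWASSummary,
    ld: LDReference,
    ridge: float = DEFAULT_RIDGE,
) -> list[TissueSignature]:
    """Impute signatures for each selected tissue with available weights."""
    out = []
    for t in tissues:
        if t not in weight_sets:
            logger.warning("no weight set for selected tissue %s; skipped", t)
            continue
        out.append(impute_signature(t, weight_sets[t], gwas, ld, ridge=ridge))
    return out
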