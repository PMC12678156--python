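"""Perturbagen signature-reversal screening.

Two independent rank statistics identify compounds whose induced expression
profiles oppose a disease signature:

* a Spearman screen — rank correlation between the disease signature
  (restricted to its top 10% of genes by |z|) and each perturbagen profile,
  calling candidates at one-sided p < 1e-4 for the alternative rho < 0;
* a Mann-Whitney reverser screen — the signature's top/bottom 150 genes are
  tested for opposite placement in each profile's genome-wide ranking, two
  directional U tests are combined into a single reverser score, and the
  top 200 profiles per tissue are called.

Candidates suggested by both screens (the intersection of perturbagen name
sets) go forward to clinical validation.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_FRACTION = 0.10
DEFAULT_ALPHA = 1e-4
DEFAULT_N_UPDOWN = 150
DEFAULT_TOP_K = 200
MIN_GENES_SPEARMAN = 20
MIN_GENES_PER_SET = 10
#: Largest n for which Spearman p is computed by exact permutation.
EXACT_PERM_MAX_N = 9
#: Largest profile size for which the reverser p is exhaustively enumerated.
EXACT_MW_MAX_N = 10

from .imputation import TissueSignature  # noqa: E402  (shared domain type)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PerturbagenProfile:
    """Per-gene induced-expression z-scores for one perturbagen/cell signature."""

    signature_id: str
    perturbagen: str
    z: pd.Series  # index: gene id

    def __post_init__(self) -> None:
        if self.z.index.duplicated().any():
            raise ValueError("duplicate gene ids in perturbagen profile")
        if len(self.z) and not np.isfinite(self.z.to_numpy(dtype=float)).all():
            raise ValueError("profile z-scores must be finite")
        self.z = self.z.astype(float)


@dataclass
class PerturbagenLibrary:
    """Gene x signature matrix plus signature metadata.

    ``matrix`` rows are genes, columns signature ids; ``meta`` has columns
    ``signature_id, perturbagen, cell_line`` aligned to the columns.
    """

    matrix: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("signature_id", "perturbagen", "cell_line"):
            if c not in self.meta.columns:
                raise ValueError(f"library metadata missing column {c!r}")
        if list(self.matrix.columns) != self.meta["signature_id"].tolist():
            raise ValueError("library matrix columns do not match metadata signature_ids")
        if self.matrix.index.duplicated().any():
            raise ValueError("duplicate gene ids in library matrix")

    def __len__(self) -> int:
        return self.matrix.shape[1]

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    def name_of(self, signature_id: str) -> str:
        row = self.meta.loc[self.meta["signature_id"] == signature_id]
        return str(row["perturbagen"].iloc[0])

    def profiles(self):
        for sid, pert in zip(self.meta["signature_id"], self.meta["perturbagen"]):
            yield PerturbagenProfile(sid, pert, self.matrix[sid])


@dataclass
class ReversalResult:
    tissue: str
    signature_id: str
    perturbagen: str
    n_genes: int
    rho: float
    p_one_sided: float


@dataclass
class CandidateSet:
    """Output of the two-screen intersection."""

    p_spearman: set[str]
    p_sigcom: set[str]
    intersection: set[str] = field(init=False)
    approved: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intersection = set(self.p_spearman) & set(self.p_sigcom)


# ---------------------------------------------------------------------------
# Gene selection
# ---------------------------------------------------------------------------

def top_fraction_genes(
    sig: TissueSignature, fraction: float = DEFAULT_FRACTION,
    min_genes: int = MIN_GENES_SPEARMAN,
) -> list[str]:
    """The floor(fraction*G) genes with largest |z|, ties broken by gene id."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    g = len(sig)
    k = math.floor(fraction * g)
    if k < min_genes:
        raise ValueError(
            f"top fraction {fraction} of {g} genes yields only {k} genes "
            f"(minimum {min_genes})"
        )
    order = sorted(sig.z.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    return [gene for gene, _ in order[:k]]


def updown_sets(
    sig: TissueSignature, n: int = DEFAULT_N_UPDOWN
) -> tuple[list[str], list[str]]:
    """Top-n upregulated and bottom-n downregulated genes by signed z.

    Ties break by gene id; when the signature has fewer than 2n genes, n is
    reduced to floor(G/2) with a warning.  The two lists are disjoint.
    """
    g = len(sig)
    if g < 2 * n:
        n = g // 2
        warnings.warn(f"signature has {g} genes; up/down set size reduced to {n}")
    order_desc = sorted(sig.z.items(), key=lambda kv: (-kv[1], kv[0]))
    up = [gene for gene, _ in order_desc[:n]]
    up_set = set(up)
    order_asc = sorted(sig.z.items(), key=lambda kv: (kv[1], kv[0]))
    down = [gene for gene, _ in order_asc if gene not in up_set][:n]
    return up, down


# ---------------------------------------------------------------------------
# Spearman reversal
# ---------------------------------------------------------------------------

def _rank_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of average ranks (Spearman rho with tie handling)."""
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    sa, sb = ra.std(), rb.std()
    if sa == 0 or sb == 0:
        raise ValueError("constant values: rank correlation undefined")
    return float(np.cov(ra, rb, bias=True)[0, 1] / (sa * sb))


def _exact_spearman_p(sig_vals: np.ndarray, prof_vals: np.ndarray, rho_obs: float) -> float:
    """Exact lower-tail permutation p over all n! relabelings of the profile."""
    n = len(sig_vals)
    rs = stats.rankdata(sig_vals)
    rp = stats.rankdata(prof_vals)
    rs_c = rs - rs.mean()
    denom = n * rs.std() * rp.std()
    perms = np.array(list(itertools.permutations(range(n))))
    rho_perm = (rp[perms] @ rs_c) / denom
    return float(np.mean(rho_perm <= rho_obs + 1e-12))


def spearman_p_one_sided(rho: float, n: int) -> float:
    """Lower-tail p for the alternative rho < 0 via the t approximation."""
    if rho >= 1.0:
        return 1.0
    if rho <= -1.0:
        return float(np.finfo(float).tiny)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(stats.t.cdf(t, n - 2))


def spearman_reversal(
    sig: TissueSignature,
    profile: PerturbagenProfile,
    genes: list[str],
    min_genes: int = MIN_GENES_SPEARMAN,
    exact_max_n: int = EXACT_PERM_MAX_N,
) -> ReversalResult | None:
    """Spearman rho and one-sided (reversal) p for one signature/profile pair.

    Uses average ranks for ties.  The p-value is an exact permutation tail
    for n <= ``exact_max_n`` and the t approximation otherwise.  Pairs with
    fewer than ``min_genes`` shared genes are skipped (returns None).
    """
    shared = [g for g in genes if g in profile.z.index]
    n = len(shared)
    if n < min_genes:
        logger.info(
            "spearman_reversal: %s/%s skipped (%d shared genes < %d)",
            sig.tissue, profile.signature_id, n, min_genes,
        )
        return None
    a = sig.z.loc[shared].to_numpy()
    b = profile.z.loc[shared].to_numpy()
    rho = _rank_corr(a, b)
    if n <= exact_max_n:
        p = _exact_spearman_p(a, b, rho)
    else:
        p = spearman_p_one_sided(rho, n)
    return ReversalResult(sig.tissue, profile.signature_id, profile.perturbagen,
                          n, rho, p)


def spearman_screen(
    signatures: list[TissueSignature],
    library: PerturbagenLibrary,
    fraction: float = DEFAULT_FRACTION,
    alpha: float = DEFAULT_ALPHA,
    min_genes: int = MIN_GENES_SPEARMAN,
) -> tuple[set[str], pd.DataFrame]:
    """Screen every (tissue, profile) pair; qualify perturbagens at p < alpha.

    A perturbagen name enters the candidate set if ANY of its tissue/profile
    pairs reaches one-sided p < alpha.  The full audit table is returned.
    Computation is vectorized across library columns; with the default
    minimum gene count the t-approximation p applies to every pair, matching
    :func:`spearman_reversal` on any single pair.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if len(library) == 0:
        raise ValueError("empty perturbagen library")
    rows = []
    for sig in signatures:
        genes = top_fraction_genes(sig, fraction, min_genes=min_genes)
        shared = [g for g in genes if g in library.genes]
        n = len(shared)
        if n < min_genes:
            logger.warning("spearman_screen: tissue %s shares only %d genes with "
                           "library; skipped", sig.tissue, n)
            continue
        ra = stats.rankdata(sig.z.loc[shared].to_numpy())
        sub = library.matrix.loc[shared].to_numpy()
        rb = stats.rankdata(sub, axis=0)
        ra_c = ra - ra.mean()
        rb_c = rb - rb.mean(axis=0)
        sa = ra.std()
        sb = rb.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = (ra_c @ rb_c) / (n * sa * sb)
        rho = np.where(sb == 0, np.nan, rho)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        p = stats.t.cdf(tstat, n - 2)
        p = np.where(rho <= -1.0, np.finfo(float).tiny, p)
        p = np.where(rho >= 1.0, 1.0, p)
        for j, sid in enumerate(library.matrix.columns):
            if np.isnan(rho[j]):
                continue
            rows.append((sig.tissue, sid, library.meta["perturbagen"].iloc[j],
                         n, float(rho[j]), float(p[j])))
    table = pd.DataFrame(
        rows, columns=["tissue", "signature_id", "perturbagen", "n_genes",
                       "rho", "p_one_sided"],
    )
    hits = table.loc[table["p_one_sided"] < alpha, "perturbagen"]
    return set(hits), table


# ---------------------------------------------------------------------------
# Mann-Whitney reverser score
# ---------------------------------------------------------------------------

def _mw_directional_z(rank_sum: float, n1: int, n2: int, tie_term: float,
                      low: bool) -> float:
    """Continuity-corrected normal z for a one-sided Mann-Whitney U test.

    ``rank_sum`` is the summed (average) rank of the focal group within the
    pooled ranking of N = n1 + n2 values.  ``low=True`` tests that the focal
    group's ranks are low; the returned z is positive in the tested
    direction.  ``tie_term`` is sum(t^3 - t) over tied groups.
    """
    n = n1 + n2
    u = rank_sum - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    sd = math.sqrt(var)
    if low:
        return (mu - u - 0.5) / sd
    return (u - mu - 0.5) / sd


def _tie_term(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _reverser_score(values: np.ndarray, up_idx: np.ndarray, down_idx: np.ndarray) -> float:
    """Stouffer-combined directional U statistics on one profile."""
    ranks = stats.rankdata(values)
    tie = _tie_term(ranks)
    n = len(values)
    z1 = _mw_directional_z(float(ranks[up_idx].sum()), len(up_idx),
                           n - len(up_idx), tie, low=True)
    z2 = _mw_directional_z(float(ranks[down_idx].sum()), len(down_idx),
                           n - len(down_idx), tie, low=False)
    return (z1 + z2) / math.sqrt(2.0)


def mw_reverser_score(
    up: list[str],
    down: list[str],
    profile: PerturbagenProfile,
    min_set: int = MIN_GENES_PER_SET,
    exact_max_n: int = EXACT_MW_MAX_N,
) -> tuple[float, float] | None:
    """Reverser score and p for one profile against up/down gene sets.

    The profile's genes are ranked ascending by induced z; one U test asks
    whether the disease-upregulated set sits at LOW ranks (the perturbagen
    pushes those genes down) and a second asks whether the downregulated set
    sits at HIGH ranks.  Each gives a continuity-corrected normal z and the
    score is their Stouffer combination (z1+z2)/sqrt(2).  p is the upper
    normal tail, or an exhaustive label-permutation tail for tiny profiles
    (N <= ``exact_max_n``), where the normal approximation is unreliable.
    """
    genes = profile.z.index
    up_in = [g for g in up if g in genes]
    down_in = [g for g in down if g in genes]
    if len(up_in) < min_set or len(down_in) < min_set:
        logger.info("mw_reverser_score: %s skipped (up=%d, down=%d < %d)",
                    profile.signature_id, len(up_in), len(down_in), min_set)
        return None
    if set(up_in) & set(down_in):
        raise ValueError("up and down gene sets overlap")
    values = profile.z.to_numpy()
    gpos = {g: i for i, g in enumerate(genes)}
    up_idx = np.array([gpos[g] for g in up_in])
    down_idx = np.array([gpos[g] for g in down_in])
    score = _reverser_score(values, up_idx, down_idx)
    n = len(values)
    if n <= exact_max_n:
        p = _exact_mw_p(values, len(up_idx), len(down_idx), score)
    else:
        p = float(stats.norm.sf(score))
    return score, p


def _exact_mw_p(values: np.ndarray, n_up: int, n_down: int, score_obs: float) -> float:
    """Exact upper-tail p of the reverser score over all up/down labelings."""
    n = len(values)
    idx = range(n)
    count = 0
    total = 0
    for up_c in itertools.combinations(idx, n_up):
        rest = [i for i in idx if i not in up_c]
        for down_c in itertools.combinations(rest, n_down):
            s = _reverser_score(values, np.array(up_c), np.array(down_c))
            total += 1
            if s >= score_obs - 1e-12:
                count += 1
    return count / total


def sigcom_screen(
    signatures: list[TissueSignature],
    library: PerturbagenLibrary,
    n: int = DEFAULT_N_UPDOWN,
    top_k: int = DEFAULT_TOP_K,
    min_set: int = MIN_GENES_PER_SET,
) -> tuple[set[str], pd.DataFrame]:
    """Per-tissue Mann-Whitney reverser ranking; union of top-k perturbagens.

    For each tissue, profiles are ranked by descending reverser score (ties
    broken by signature_id) and the top ``top_k`` qualify; the candidate set
    is the union of qualifying perturbagen names over tissues.
    """
    if len(library) == 0:
        raise ValueError("empty perturbagen library")
    if len(library) < top_k:
        warnings.warn(
            f"library has {len(library)} profiles < top_k={top_k}; all returned"
        )
    rows = []
    names: set[str] = set()
    for sig in signatures:
        up, down = updown_sets(sig, n)
        scored = []
        for prof in library.profiles():
            res = mw_reverser_score(up, down, prof, min_set=min_set)
            if res is None:
                continue
            score, p = res
            scored.append((prof.signature_id, prof.perturbagen, score, p))
        scored.sort(key=lambda r: (-r[2], r[0]))
        for rank, (sid, pert, score, p) in enumerate(scored, start=1):
            rows.append((sig.tissue, sid, pert, score, p, rank, rank <= top_k))
            if rank <= top_k:
                names.add(pert)
    table = pd.DataFrame(
        rows, columns=["tissue", "signature_id", "perturbagen", "score", "p",
                       "rank", "selected"],
    )
    return names, table


# ---------------------------------------------------------------------------
# Candidate intersection
# ---------------------------------------------------------------------------

def intersect_candidates(
    p_spearman: set[str], p_sigcom: set[str], drug_map: pd.DataFrame | None = None
) -> CandidateSet:
    """Intersect the two screens and map to approved drugs.

    ``drug_map`` columns: perturbagen, approved (yes/no), drug_name,
    drug_class.  Unmapped perturbagens are treated as non-approved.  The
    approved list is deduplicated by drug name, ordered by drug name.
    """
    cs = CandidateSet(set(p_spearman), set(p_sigcom))
    if drug_map is not None:
        dm = drug_map.set_index("perturbagen")
        seen: dict[str, str] = {}
        for name in sorted(cs.intersection):
            if name in dm.index:
                row = dm.loc[name]
                if str(row["approved"]).strip().lower() in {"yes", "true", "1"}:
                    seen.setdefault(str(row["drug_name"]), str(row["drug_class"]))
        cs.approved = sorted(seen.items())
    return cs
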