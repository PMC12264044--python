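"""Label-free proteomics stage: differential sets, secretome, interactome.

Pipeline from a protein × sample abundance matrix (three cell classes —
capsular/trabecular myofibroblasts CTM, Lin⁻CD45⁻ stromal cells STC, and
Lin⁻Sca-1⁺c-kit⁺ progenitors LSK, with technical-replicate runs) to:
technical-replicate averaging, lowest-detected-value imputation,
per-protein differential abundance on log2 intensities with
Benjamini-Hochberg correction (enriched = fold change > 2 and adjusted
p < 0.05), three-way Venn counts, the secreted subset by annotation,
membership-based pathway classification, and a ligand→receptor interaction
score with a label-permutation p-value (dimer receptors use the minimum
over monomers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthgeom import AbundanceMatrix

__all__ = [
    "AnnotationBundle",
    "collapse_technical",
    "impute_lowest",
    "differential_abundance",
    "pairwise_sets",
    "secretome_subset",
    "pathway_classes",
    "interaction_scores",
]

log = logging.getLogger(__name__)


class LabelError(ValueError):
    """Inconsistent sample labels."""


class ImputationError(ValueError):
    """Nothing detected to impute from."""


class DesignError(ValueError):
    """Too few samples per group."""


class AnnotationError(ValueError):
    """Missing annotation table."""


@dataclass
class AnnotationBundle:
    """Protein annotations: secretory flag, pathway map, ligand-receptor pairs.

    ``secretory``: protein → bool.  ``pathways``: DataFrame with columns
    protein, pathway_id (one row per membership).  ``lr_pairs``: DataFrame
    with columns ligand, receptor_monomers (list of receiver-side
    monomers; a heterodimer lists several).
    """

    secretory: dict[str, bool]
    pathways: pd.DataFrame
    lr_pairs: pd.DataFrame


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def collapse_technical(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Average technical replicates into biological-sample columns.

    Missing runs are ignored in the mean; an entry stays missing only when
    every run of that biological sample missed it.
    """
    meta = matrix.samples
    for c in ("cell_type", "biorep"):
        if c not in meta.columns:
            raise LabelError(f"sample table lacks {c!r}")
    key = meta["cell_type"].astype(str) + "_" + meta["biorep"].astype(str)
    counts = key.value_counts()
    if "techrep" in meta.columns:
        # an orphan would be a biological sample appearing with a single run
        # while the design declares several; only flag inconsistent keys
        sizes = counts.unique()
        if len(sizes) > 1:
            raise LabelError(
                f"unbalanced technical replication across samples: {dict(counts)}")
    grouped = matrix.values.T.groupby(key.loc[matrix.values.columns]).mean().T
    new_meta = (meta.assign(_key=key).drop_duplicates("_key")
                .set_index("_key")[["cell_type", "biorep"]])
    new_meta = new_meta.loc[grouped.columns]
    new_meta.index.name = "sample"
    return AbundanceMatrix(values=grouped, samples=new_meta, truth=matrix.truth)


def impute_lowest(matrix: AbundanceMatrix, *, scope: str = "global") -> AbundanceMatrix:
    """Replace still-missing entries by the lowest detected abundance.

    ``scope='global'`` (default) uses the matrix-wide minimum detected
    intensity; ``scope='protein'`` uses each protein's own minimum (rows
    never detected anywhere fall back to the global minimum).  Detected
    values are never changed, so the operation is idempotent.
    """
    vals = matrix.values
    if not np.isfinite(vals.to_numpy(float)).any():
        raise ImputationError("matrix has no detected values")
    global_min = np.nanmin(vals.to_numpy(float))
    if scope == "global":
        filled = vals.fillna(global_min)
    elif scope == "protein":
        row_min = vals.min(axis=1).fillna(global_min)
        filled = vals.T.fillna(row_min).T
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return AbundanceMatrix(values=filled, samples=matrix.samples,
                           truth=matrix.truth)


# --------------------------------------------------------------------------
# differential abundance
# --------------------------------------------------------------------------

def _moderate_variance(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-protein variances.

    Method-of-moments fit of a scaled inverse-chi-square prior to the
    observed log variances, following the standard moderated-t
    construction; returns posterior variances and the added prior df.
    """
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    from scipy.special import polygamma, digamma

    e_z = z.mean()
    var_z = z.var(ddof=1)
    rhs = var_z - polygamma(1, df / 2)
    if rhs <= 0:
        d0 = np.inf
        s0_2 = np.exp(e_z - digamma(df / 2) + np.log(df / 2))
        post = np.full_like(s2, s0_2)
        return post, d0
    # solve trigamma(d0/2) = rhs by Newton on x = d0/2
    x = 0.5 + 1.0 / rhs
    for _ in range(50):
        f = polygamma(1, x) - rhs
        x -= f / polygamma(2, x)
        x = max(x, 1e-3)
    d0 = 2 * x
    s0_2 = np.exp(e_z + digamma(df / 2) - np.log(df / 2)
                  - digamma(x) + np.log(x))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0


def differential_abundance(matrix: AbundanceMatrix, group_a: str, group_b: str,
                           *, moderated: bool = False,
                           fc_threshold: float = 2.0,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-protein differential abundance of ``group_a`` vs ``group_b``.

    Two-sample equal-variance t on log2 intensities (optionally with
    empirical-Bayes variance shrinkage), BH adjustment across all tested
    proteins, fold change as the ratio of group geometric means.  A
    protein is ``enriched`` when |FC| > ``fc_threshold`` on the linear
    scale (strictly greater) and adjusted p < ``alpha``; the direction
    flags split that by sign.  The matrix must be imputed (no NaN) so the
    log transform needs no pseudocount.
    """
    cols_a = matrix.columns_for(group_a)
    cols_b = matrix.columns_for(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise DesignError(f"need >= 2 samples per group; got "
                          f"{len(cols_a)} vs {len(cols_b)}")
    A = np.log2(matrix.values[cols_a].to_numpy(float))
    B = np.log2(matrix.values[cols_b].to_numpy(float))
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValueError("matrix contains missing or non-positive values; "
                         "run impute_lowest first")
    na, nb = A.shape[1], B.shape[1]
    mean_a, mean_b = A.mean(1), B.mean(1)
    log2fc = mean_a - mean_b
    var_a = A.var(1, ddof=1)
    var_b = B.var(1, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / df
    if moderated:
        sp2, d0 = _moderate_variance(sp2, df)
        df_t = df + (d0 if np.isfinite(d0) else 0.0)
    else:
        df_t = df
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se
    zero_se = se == 0
    with np.errstate(invalid="ignore"):
        t[zero_se] = np.where(log2fc[zero_se] == 0, 0.0,
                              np.sign(log2fc[zero_se]) * np.inf)
    p = 2 * stats.t.sf(np.abs(t), df_t)
    p = np.where(np.isnan(p), 1.0, np.clip(p, 0.0, 1.0))
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    thr = np.log2(fc_threshold)
    up = (log2fc > thr) & (padj < alpha)
    down = (log2fc < -thr) & (padj < alpha)
    return pd.DataFrame({
        "log2fc": log2fc, "t": t, "p": p, "p_adj": padj,
        "enriched_up": up, "enriched_down": down,
        "enriched": up | down,
    }, index=matrix.values.index.rename("protein"))


def pairwise_sets(detables: dict[str, pd.DataFrame],
                  *, direction: str = "enriched") -> dict:
    """Venn counts over the differential sets of the three pairwise contrasts.

    ``detables`` maps a contrast name to its DE table; ``direction``
    selects which flag defines membership (``enriched``, ``enriched_up``
    or ``enriched_down``).
    """
    sets = {name: set(t.index[t[direction]]) for name, t in detables.items()}
    names = list(sets)
    out = {"sets": {n: sorted(s) for n, s in sets.items()}, "counts": {}}
    counts = out["counts"]
    universe = set().union(*sets.values()) if sets else set()
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for n in combo:
                inside &= sets[n]
            for n in names:
                if n not in combo:
                    inside -= sets[n]
            counts["&".join(combo)] = len(inside)
    return out


# --------------------------------------------------------------------------
# secretome / pathways
# --------------------------------------------------------------------------

def secretome_subset(enriched: set[str], ann: AnnotationBundle) -> set[str]:
    """Enriched proteins annotated as secreted; unannotated → non-secretory."""
    missing = [p for p in enriched if p not in ann.secretory]
    if missing:
        log.info("%d enriched protein(s) lack a secretory annotation; "
                 "treated as non-secretory", len(missing))
    return {p for p in enriched if ann.secretory.get(p, False)}


def pathway_classes(ctm_secretome: set[str], stc_secretome: set[str],
                    lsk_proteins: set[str], ann: AnnotationBundle) -> pd.DataFrame:
    """Classify LSK-detected pathways by which niche secretome reaches them.

    A pathway is "detected in LSK" when at least one LSK-detected protein
    maps to it; it is CTM-regulated (resp. STC-) when at least one
    CTM-enriched (resp. STC-enriched) secreted protein maps to it.
    Classes: CTM_only / STC_only / common / neither.  The returned table
    has one row per detected pathway plus the contributing ligand lists
    (the chord matrix of secreted protein → pathway links).
    """
    if ann.pathways is None or len(ann.pathways) == 0:
        raise AnnotationError("empty pathway map")
    pw = ann.pathways
    by_pathway = pw.groupby("pathway_id")["protein"].apply(set)
    rows = []
    for pid, members in by_pathway.items():
        if not (members & lsk_proteins):
            continue
        ctm_lig = sorted(members & ctm_secretome)
        stc_lig = sorted(members & stc_secretome)
        if ctm_lig and stc_lig:
            cls = "common"
        elif ctm_lig:
            cls = "CTM_only"
        elif stc_lig:
            cls = "STC_only"
        else:
            cls = "neither"
        rows.append(dict(pathway_id=pid, klass=cls,
                         ctm_ligands=";".join(ctm_lig),
                         stc_ligands=";".join(stc_lig)))
    return pd.DataFrame(rows).rename(columns={"klass": "class"})


# --------------------------------------------------------------------------
# interaction scoring
# --------------------------------------------------------------------------

def interaction_scores(matrix: AbundanceMatrix, lr_pairs: pd.DataFrame,
                       niche_type: str, receiver_type: str = "LSK",
                       n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Ligand-receptor interaction scores with a permutation p-value.

    score = mean( mean log2 ligand abundance in the sender cell type,
    receptor-side mean log2 abundance in the receiver, where a dimer
    receptor takes the minimum over its monomers ).  The null shuffles the
    sample cell-type labels ``n_perm`` times; p is the one-sided fraction
    of permuted scores ≥ the observed one.  Pairs whose ligand is
    undetected in every sender sample, or with any receptor monomer
    undetected in every receiver sample, are dropped with a log entry.
    Deterministic per seed and invariant to sample order.
    """
    if n_perm < 100:
        log.warning("n_perm=%d gives a coarse permutation p-value", n_perm)
    rng = np.random.default_rng(seed)
    vals = matrix.values
    meta = matrix.samples
    sender_cols = matrix.columns_for(niche_type)
    receiver_cols = matrix.columns_for(receiver_type)
    if not sender_cols or not receiver_cols:
        raise DesignError("sender or receiver cell type absent from the matrix")

    # work in log2; operate on the two cell types' pooled samples
    pool_cols = sorted(sender_cols) + sorted(receiver_cols)
    X = np.log2(vals[pool_cols].to_numpy(float))
    is_sender = np.array([c in sender_cols for c in pool_cols])
    n_sender = int(is_sender.sum())

    perms = np.empty((n_perm, len(pool_cols)), dtype=int)
    for i in range(n_perm):
        perms[i] = rng.permutation(len(pool_cols))

    rows = []
    index = {p: i for i, p in enumerate(vals.index)}
    for _, pair in lr_pairs.iterrows():
        ligand = pair["ligand"]
        monomers = pair["receptor_monomers"]
        if isinstance(monomers, str):
            monomers = monomers.split(";")
        if ligand not in index or any(m not in index for m in monomers):
            log.info("pair %s -> %s skipped: protein not in matrix",
                     ligand, "+".join(monomers))
            continue
        lig_row = X[index[ligand]]
        mono_rows = X[[index[m] for m in monomers]]
        if not np.isfinite(lig_row[is_sender]).any() or any(
                not np.isfinite(mono_rows[k][~is_sender]).any()
                for k in range(len(monomers))):
            log.info("pair %s -> %s dropped: undetected partner",
                     ligand, "+".join(monomers))
            continue

        def score(sender_mask):
            lig = np.nanmean(lig_row[sender_mask])
            rec = np.nanmin([np.nanmean(mono_rows[k][~sender_mask])
                             for k in range(len(monomers))])
            return 0.5 * (lig + rec)

        obs = score(is_sender)
        null = np.empty(n_perm)
        for i in range(n_perm):
            mask = np.zeros(len(pool_cols), bool)
            mask[perms[i][:n_sender]] = True
            null[i] = score(mask)
        p = float((np.sum(null >= obs) + 1) / (n_perm + 1))
        rows.append(dict(ligand=ligand, receptor="+".join(monomers),
                         sender=niche_type, receiver=receiver_type,
                         score=float(obs), p=p))
    return pd.DataFrame(rows)
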