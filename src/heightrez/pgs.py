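"""Polygenic-score engine: weight-table parsing, allele matching, scoring.

The score for participant *i* is ``sum_j w_j * d_ij`` over the SNPs whose
alleles could be reconciled with the genotype metadata, where ``d_ij`` is the
dosage of the weight table's effect allele (the raw dosage, or ``2 - dosage``
when the effect allele is the metadata's second allele). SNPs absent from the
metadata or with irreconcilable alleles are excluded and reported, mirroring
standard scoring-tool behaviour (PLINK ``--score``). Missing dosages
contribute the SNP's mean dosage ``2 * effect-allele frequency``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .synth import GenotypeMatrix

AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}

DEFAULT_COLUMNS = ("variant_id", "effect_allele", "other_allele", "weight")


@dataclass
class WeightTable:
    """Per-SNP effect alleles and weights (height SD per effect-allele dose)."""

    table: pd.DataFrame  # variant_id, effect_allele, other_allele, weight

    def __len__(self):
        return len(self.table)


@dataclass
class MatchedWeights:
    """Weights aligned to genotype column order, with exclusion report."""

    snp_index: np.ndarray        # genotype column indices of kept SNPs
    weights: np.ndarray          # aligned weights
    flip: np.ndarray             # bool: dosage counted on metadata allele2
    excluded: pd.DataFrame       # variant_id, reason in {absent, allele-mismatch,
                                 #                        strand-ambiguous}

    def __post_init__(self):
        if self.flip.shape != self.weights.shape:
            raise DataError("flip mask and weight vector must align")


def read_weight_table(path, columns=DEFAULT_COLUMNS, sep="\t") -> WeightTable:
    """Parse a PLINK ``--score``-style TSV of per-SNP weights.

    ``columns`` names the (variant id, effect allele, other allele, weight)
    columns in the file. Malformed rows are reported with 1-based line
    numbers (header is line 1).
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"weight table missing columns: {missing}")
    vid, ea, oa, wcol = columns
    w = pd.to_numeric(df[wcol], errors="coerce")
    bad = df.index[w.isna() & df[wcol].notna()] + 2  # file line numbers
    if len(bad):
        raise DataError(f"non-numeric weight on line(s) {list(bad)}")
    if df[wcol].isna().any():
        raise DataError(
            f"empty weight on line(s) {list(df.index[df[wcol].isna()] + 2)}")
    dup = df[vid][df[vid].duplicated()].unique()
    if len(dup):
        raise DataError(f"duplicate variant_id(s): {sorted(dup)}")
    same = df[ea].str.upper() == df[oa].str.upper()
    if same.any():
        raise DataError(
            f"effect_allele == other_allele on line(s) {list(df.index[same] + 2)}")
    out = pd.DataFrame({
        "variant_id": df[vid],
        "effect_allele": df[ea].str.upper(),
        "other_allele": df[oa].str.upper(),
        "weight": w.astype(float),
    })
    return WeightTable(out)


def match_alleles(weights: WeightTable, snp_meta: pd.DataFrame,
                  drop_ambiguous: bool = False) -> MatchedWeights:
    """Reconcile weight-table alleles with genotype metadata.

    A SNP is kept when ``{effect, other}`` equals ``{allele1, allele2}`` as a
    set; ``flip`` is set when the effect allele is ``allele2`` (dosage counts
    ``allele1``). SNPs absent from the metadata or with a different allele
    pair are excluded with a per-SNP reason; with ``drop_ambiguous``,
    strand-ambiguous A/T and C/G SNPs are excluded too. Exclusion is never
    fatal.
    """
    meta = snp_meta.reset_index(drop=True)
    col_of = {v: i for i, v in enumerate(meta["variant_id"])}
    a1 = meta["allele1"].str.upper().to_numpy()
    a2 = meta["allele2"].str.upper().to_numpy()

    keep_idx, keep_w, keep_flip = [], [], []
    excl_id, excl_reason = [], []
    for vid, ea, oa, w in weights.table.itertuples(index=False):
        j = col_of.get(vid)
        if j is None:
            excl_id.append(vid)
            excl_reason.append("absent")
            continue
        if drop_ambiguous and frozenset({ea, oa}) in AMBIGUOUS_PAIRS:
            excl_id.append(vid)
            excl_reason.append("strand-ambiguous")
            continue
        if ea == a1[j] and oa == a2[j]:
            flip = False
        elif ea == a2[j] and oa == a1[j]:
            flip = True
        else:
            excl_id.append(vid)
            excl_reason.append("allele-mismatch")
            continue
        keep_idx.append(j)
        keep_w.append(w)
        keep_flip.append(flip)

    return MatchedWeights(
        snp_index=np.asarray(keep_idx, dtype=np.int64),
        weights=np.asarray(keep_w, dtype=np.float64),
        flip=np.asarray(keep_flip, dtype=bool),
        excluded=pd.DataFrame({"variant_id": excl_id, "reason": excl_reason}),
    )


def compute_pgs(genotypes: GenotypeMatrix, matched: MatchedWeights) -> np.ndarray:
    """Per-participant polygenic score over the matched SNPs.

    Dosages are flipped to the effect allele where needed; a missing dosage
    (NaN) contributes ``w_j * 2 * effect-allele frequency`` with the
    frequency taken from the genotype matrix (mean imputation).
    """
    if len(matched.weights) == 0:
        return np.zeros(genotypes.n)
    d = genotypes.dosages[:, matched.snp_index].astype(float, copy=True)
    finite = np.isfinite(d)
    vals = d[finite]
    if ((vals < 0) | (vals > 2)).any():
        i, j = [a[0] for a in np.where(np.isfinite(d) & ((d < 0) | (d > 2)))]
        raise DataError(
            f"dosage outside [0,2] for participant {genotypes.ids[i]} at SNP "
            f"{genotypes.snp_meta['variant_id'].iloc[matched.snp_index[j]]}")
    d[:, matched.flip] = 2.0 - d[:, matched.flip]
    if not finite.all():
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(d, axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        idx = np.where(~finite)
        d[idx] = col_mean[idx[1]]
    return d @ matched.weights


def write_scores(ids, scores, path):
    pd.DataFrame({"id": ids, "pgs": scores}).to_csv(path, sep="\t", index=False)
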