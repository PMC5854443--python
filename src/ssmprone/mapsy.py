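"""Quantification of pooled splicing-reporter assays.

The entry point is a table of read counts: every wild-type/mutant pair of
reporter species has an input count and a spliced-output count per assay
(in vivo transfection, in vitro nuclear extract), and optionally per
spliceosomal fraction (E, A, B/C complexes, released mRNA and lariat).

Three statistics are computed:

* per-species splicing efficiency, log2 of the species' share of the spliced
  pool over its share of the input pool;
* the wild-type/mutant allelic ratio per fraction, log2 of the two alleles'
  input-normalised enrichments;
* ESM calls: a mutant allele is an exonic splicing mutation when its allelic
  fold change exceeds a threshold in *both* assays and a count-based
  two-proportion test survives Benjamini-Hochberg FDR control within the
  panel, in both assays.

A pseudocount (default 0.5) is added to every raw count before any ratio, so
zero counts never produce infinities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PSEUDOCOUNT = 0.5

# Spliceosome assembly order; mRNA and lariat are the released products.
FRACTION_ORDER = ("E", "A", "B/C", "mRNA", "lariat")
_TRANSITION = {"E": "E->A", "A": "A->B", "B/C": "B->mRNA"}


def splicing_efficiency(counts: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT,
                        inp_col: str = "inp", spl_col: str = "spl") -> pd.Series:
    """Per-species log2 splicing efficiency over one library pool.

    efficiency_i = log2( (spl_i / sum spl) / (inp_i / sum inp) ), computed
    after adding ``pseudocount`` to every raw count. The statistic is
    invariant to global rescaling of either pool.
    """
    if len(counts) == 0:
        raise ValueError("empty count table")
    spl = counts[spl_col].to_numpy(dtype=float)
    inp = counts[inp_col].to_numpy(dtype=float)
    if (spl < 0).any() or (inp < 0).any():
        raise ValueError("negative counts")
    if spl.sum() == 0:
        raise ValueError("no spliced output in the pool")
    if inp.sum() == 0:
        raise ValueError("no input reads in the pool")
    spl = spl + pseudocount
    inp = inp + pseudocount
    eff = np.log2((spl / spl.sum()) / (inp / inp.sum()))
    return pd.Series(eff, index=counts.index, name="efficiency")


def allelic_ratio(mi_e: float, mi_i: float, mj_e: float, mj_i: float,
                  pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2 minor/major allelic ratio of input-normalised enrichments.

    ``mi_e``/``mi_i`` are the minor allele's counts in the selected pool and
    the input; ``mj_e``/``mj_i`` the major allele's. Swapping the two alleles
    flips the sign exactly.
    """
    for v in (mi_e, mi_i, mj_e, mj_i):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError("missing count for allelic ratio")
        if v < 0:
            raise ValueError("negative count")
    pc = pseudocount
    return float(np.log2(((mi_e + pc) / (mi_i + pc)) / ((mj_e + pc) / (mj_i + pc))))


def assign_major_allele(fractions: pd.DataFrame,
                        pseudocount: float = DEFAULT_PSEUDOCOUNT) -> str:
    """Pick the major allele of one pair from the released-mRNA fraction.

    The allele that splices more efficiently (larger input-normalised share
    of the mRNA fraction) is the major allele. ``fractions`` holds one row
    per (allele, fraction) with columns allele, fraction, sel, inp.
    """
    sub = fractions[fractions["fraction"] == "mRNA"]
    if sub.empty:
        raise ValueError("mRNA fraction required to assign the major allele")
    enr = {}
    for row in sub.itertuples(index=False):
        enr[row.allele] = (row.sel + pseudocount) / (row.inp + pseudocount)
    if set(enr) != {"wt", "mt"}:
        raise ValueError("both wt and mt rows required in the mRNA fraction")
    return "wt" if enr["wt"] >= enr["mt"] else "mt"


def fraction_ratios(fractions: pd.DataFrame,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.Series:
    """Mutant-vs-wild-type log2 allelic ratio in every spliceosomal fraction.

    Positive values mean the mutant allele is over-represented (retained) in
    that fraction relative to its input share.
    """
    out = {}
    for frac, sub in fractions.groupby("fraction"):
        rows = {r.allele: r for r in sub.itertuples(index=False)}
        if set(rows) != {"wt", "mt"}:
            raise ValueError(f"fraction {frac!r}: need exactly one wt and one mt row")
        out[frac] = allelic_ratio(rows["mt"].sel, rows["mt"].inp,
                                  rows["wt"].sel, rows["wt"].inp, pseudocount)
    return pd.Series(out, name="log2_ratio")


# ---------------------------------------------------------------------------
# ESM calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EsmCall:
    pair_id: str
    ratios: dict  # assay -> log2 mt/wt allelic ratio
    call: str     # 'ESM' | 'no-effect' | 'indeterminate'


def _pair_assay_stats(counts: pd.DataFrame, pseudocount: float) -> pd.DataFrame:
    """Per (pair, assay): log2 allelic ratio and two-proportion test p."""
    rows = []
    for (pid, assay), sub in counts.groupby(["pair_id", "assay"], sort=True):
        alleles = {r.allele: r for r in sub.itertuples(index=False)}
        if set(alleles) != {"wt", "mt"}:
            raise ValueError(f"pair {pid} assay {assay}: need one wt and one mt row")
        wt, mt = alleles["wt"], alleles["mt"]
        if wt.inp == 0 or mt.inp == 0:
            rows.append((pid, assay, np.nan, np.nan, True))
            continue
        ratio = allelic_ratio(mt.spl, mt.inp, wt.spl, wt.inp, pseudocount)
        table = np.array([[wt.spl, wt.inp], [mt.spl, mt.inp]], dtype=float)
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            p = 1.0
        else:
            p = float(stats.chi2_contingency(table + 0.5, correction=False).pvalue)
        rows.append((pid, assay, ratio, p, False))
    return pd.DataFrame(rows, columns=["pair_id", "assay", "ratio", "p", "indeterminate"])


def call_esm(counts: pd.DataFrame, fold_threshold: float = 1.5,
             fdr: float = 0.05, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Call exonic splicing mutations over a whole panel of wt/mt pairs.

    A pair is an ESM when, in *every* assay present, the absolute log2
    allelic ratio is at least log2(``fold_threshold``) and the count-based
    test is significant after Benjamini-Hochberg correction (level ``fdr``)
    across the panel within that assay. Pairs missing an assay or with a
    zero input count for either allele are 'indeterminate'.

    Returns a frame indexed by pair_id with one ratio column per assay,
    ``call`` and per-assay q-values.
    """
    st = _pair_assay_stats(counts, pseudocount)
    assays = sorted(st["assay"].unique())
    if not assays:
        raise ValueError("empty count table")
    st["q"] = np.nan
    for assay in assays:
        m = (st["assay"] == assay) & ~st["indeterminate"]
        if m.any():
            st.loc[m, "q"] = stats.false_discovery_control(st.loc[m, "p"].to_numpy(), method="bh")

    wide_r = st.pivot(index="pair_id", columns="assay", values="ratio")
    wide_q = st.pivot(index="pair_id", columns="assay", values="q")
    wide_ind = st.pivot(index="pair_id", columns="assay", values="indeterminate")

    log2_thr = np.log2(fold_threshold)
    indeterminate = wide_ind.isna().any(axis=1) | wide_ind.fillna(True).any(axis=1)
    passes = (wide_r.abs() >= log2_thr).all(axis=1) & (wide_q <= fdr).all(axis=1)
    call = np.where(indeterminate, "indeterminate", np.where(passes, "ESM", "no-effect"))

    out = wide_r.rename(columns=lambda a: f"ratio_{a}")
    for assay in assays:
        out[f"q_{assay}"] = wide_q[assay]
    out["call"] = call
    return out


# ---------------------------------------------------------------------------
# Spliceosomal-complex blockage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockageProfile:
    """Mutant retention per spliceosomal fraction and the inferred blocks.

    ``retention_pct`` is the percent representation of the mutant allele in
    each fraction relative to the wild type (wild type = 100%), from the
    input-normalised allelic ratio. A stage is blocked when the mutant
    accumulates there while a downstream fraction is depleted; ``primary``
    is the blocked stage with maximal retention, or 'no block'.
    """

    retention_pct: pd.Series
    blocked: tuple[str, ...]
    primary: str


def complex_blockage(fractions: pd.DataFrame,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT,
                     accumulation_pct: float = 120.0,
                     depletion_pct: float = 80.0) -> BlockageProfile:
    """Infer which spliceosome-assembly transitions a mutant allele blocks.

    ``fractions`` holds rows (allele, fraction, sel, inp) for one pair over
    at least two of the fractions E, A, B/C, mRNA, lariat. Accumulation of
    the mutant in an intermediate complex together with depletion in any
    later fraction flags a block at the next transition; a pair may flag
    several stages. A monotone profile with no accumulation is 'no block'.
    """
    present = [f for f in FRACTION_ORDER if f in set(fractions["fraction"])]
    if len(present) < 2:
        raise ValueError("need at least two spliceosomal fractions")
    ratios = fraction_ratios(fractions, pseudocount)
    retention = (100.0 * 2.0 ** ratios).reindex(present)

    blocked = []
    for i, frac in enumerate(present):
        if frac in ("mRNA", "lariat"):
            continue
        downstream = retention.iloc[i + 1:]
        if len(downstream) == 0:
            continue
        if retention[frac] >= accumulation_pct and downstream.min() <= depletion_pct:
            blocked.append(frac)
    if blocked:
        primary = _TRANSITION[max(blocked, key=lambda f: retention[f])]
        blocked_t = tuple(_TRANSITION[f] for f in blocked)
    else:
        primary, blocked_t = "no block", ()
    return BlockageProfile(retention_pct=retention, blocked=blocked_t, primary=primary)
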