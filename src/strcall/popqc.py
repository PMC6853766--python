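"""Population-statistics genotype QC for biparental families.

Without a gold standard, a biparental family's structure predicts
allele and genotype frequencies, so inconsistent genotype calls can be
flagged as errors. Two designs are covered:

* outbred F1 (one-generation cross of heterozygous parents): each
  biallelic variant is assigned a parental configuration; offspring
  genotypes impossible under that configuration (e.g. BB under AAxAB)
  are errors, and calls at variants with at least one segregating
  parent are usable for genetic-map construction.
* inbred biparental (e.g. an F6 from single-seed descent): variants
  with both parents homozygous for different alleles, minor allele
  frequency > 0.1 and heterozygous fraction < 0.1 form the sensitivity
  set; heterozygous calls inside that set, and minor-allele calls at
  variants with MAF < 0.1, are errors.

Both reports are swept over minimum-GQ thresholds: calls below the
threshold are set to missing and all statistics recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .core import VariantRecord

DEFAULT_GQ_GRID = tuple(range(0, 91, 10))

# genotype codes: 0 = hom first allele, 1 = het, 2 = hom second allele, -1 = missing
_OUTBRED_POSSIBLE = {
    (0, 0): {0},
    (0, 1): {0, 1}, (1, 0): {0, 1},
    (1, 1): {0, 1, 2},
    (0, 2): {1}, (2, 0): {1},
    (1, 2): {1, 2}, (2, 1): {1, 2},
    (2, 2): {2},
}
_OUTBRED_EXPECTED = {
    (0, 1): (0.5, 0.5, 0.0), (1, 0): (0.5, 0.5, 0.0),
    (1, 1): (0.25, 0.5, 0.25),
    (0, 2): (0.0, 1.0, 0.0), (2, 0): (0.0, 1.0, 0.0),
    (1, 2): (0.0, 0.5, 0.5), (2, 1): (0.0, 0.5, 0.5),
    (0, 0): (1.0, 0.0, 0.0), (2, 2): (0.0, 0.0, 1.0),
}
# a variant is usable for a genetic map when the cross segregates
_OUTBRED_USABLE = {(0, 1), (1, 0), (1, 1), (0, 2), (2, 0), (1, 2), (2, 1)}


@dataclass
class FamilyQCReport:
    table: pd.DataFrame  # columns: threshold, usable_calls, errors

    def at(self, threshold: int) -> pd.Series:
        return self.table[self.table.threshold == threshold].iloc[0]


def _genotype_matrix(
    records: list[VariantRecord], samples: list[str]
) -> tuple[np.ndarray, np.ndarray, list[VariantRecord]]:
    """(genotype codes, GQ) arrays over biallelic records; non-biallelic
    records are skipped."""
    kept = [r for r in records if len(r.alt_alleles) == 1]
    geno = np.full((len(kept), len(samples)), -1, dtype=int)
    gq = np.zeros((len(kept), len(samples)), dtype=int)
    for vi, r in enumerate(kept):
        for si, s in enumerate(samples):
            call = r.call(s)
            if call.is_missing:
                continue
            geno[vi, si] = call.allele_pair[0] + call.allele_pair[1]
            gq[vi, si] = call.gq
    return geno, gq, kept


def infer_parental_configuration(
    offspring: np.ndarray, p_gate: float = 0.01, error_rate: float = 0.01
) -> tuple[int, int] | None:
    """Maximum-likelihood parental configuration from offspring genotype
    frequencies, gated by a chi-square goodness-of-fit test (p > p_gate).

    Used when a parent's genotype is unavailable. Returns None when no
    segregating configuration fits.
    """
    called = offspring[offspring >= 0]
    if len(called) == 0:
        return None
    counts = np.bincount(called, minlength=3).astype(float)
    best, best_ll = None, -np.inf
    for cfg in sorted(_OUTBRED_USABLE):
        exp = np.array(_OUTBRED_EXPECTED[cfg])
        probs = (1 - error_rate) * exp + error_rate / 3.0
        ll = float((counts * np.log(probs)).sum())
        if ll > best_ll:
            best, best_ll = cfg, ll
    exp = np.array(_OUTBRED_EXPECTED[best])
    support = exp > 0
    if counts[~support].sum() > 0.05 * counts.sum():
        return None
    sub = counts[support]
    if sub.sum() == 0:
        return None
    chi = sp_stats.chisquare(sub, f_exp=exp[support] / exp[support].sum() * sub.sum())
    if chi.pvalue <= p_gate and len(sub) > 1:
        return None
    return best


def qc_outbred_f1(
    records: list[VariantRecord],
    samples: list[str],
    parent_ids: tuple[str, str] = ("P1", "P2"),
    gq_grid: tuple[int, ...] = DEFAULT_GQ_GRID,
) -> FamilyQCReport:
    """Usable-call and inferred-error counts per minimum-GQ threshold for
    an outbred F1 family."""
    geno, gq, _ = _genotype_matrix(records, samples)
    p_idx = [samples.index(p) for p in parent_ids]
    o_idx = [i for i in range(len(samples)) if i not in p_idx]
    rows = []
    for thr in gq_grid:
        g = np.where(gq >= thr, geno, -1)
        usable = 0
        errors = 0
        for vi in range(g.shape[0]):
            p1, p2 = int(g[vi, p_idx[0]]), int(g[vi, p_idx[1]])
            off = g[vi, o_idx]
            called = off[off >= 0]
            if p1 >= 0 and p2 >= 0:
                cfg = (p1, p2)
            else:
                cfg = infer_parental_configuration(off)
                if cfg is None:
                    continue
            possible = _OUTBRED_POSSIBLE[cfg]
            errors += int(sum(1 for x in called if int(x) not in possible))
            if cfg in _OUTBRED_USABLE:
                usable += len(called)
        rows.append({"threshold": thr, "usable_calls": usable, "errors": errors})
    return FamilyQCReport(pd.DataFrame(rows))


def qc_inbred_biparental(
    records: list[VariantRecord],
    samples: list[str],
    parent_ids: tuple[str, str] = ("P1", "P2"),
    gq_grid: tuple[int, ...] = DEFAULT_GQ_GRID,
    het_mode: str = "observed",
) -> FamilyQCReport:
    """Usable-call and inferred-error counts per minimum-GQ threshold for
    an inbred biparental family.

    ``het_mode`` selects the heterozygosity statistic gating the
    sensitivity set: "observed" (fraction of called genotypes that are
    heterozygous, the default) or "hardy_weinberg" (2p(1-p)).
    """
    for p in parent_ids:
        if p not in samples:
            raise ValueError(f"parent {p!r} missing from sample list")
    geno, gq, _ = _genotype_matrix(records, samples)
    p_idx = [samples.index(p) for p in parent_ids]
    o_idx = [i for i in range(len(samples)) if i not in p_idx]
    rows = []
    for thr in gq_grid:
        g = np.where(gq >= thr, geno, -1)
        usable = 0
        errors = 0
        for vi in range(g.shape[0]):
            row = g[vi]
            called = row[row >= 0]
            if len(called) == 0:
                continue
            alt_freq = called.sum() / (2 * len(called))
            maf = min(alt_freq, 1 - alt_freq)
            het = (
                (called == 1).sum() / len(called)
                if het_mode == "observed"
                else 2 * alt_freq * (1 - alt_freq)
            )
            off = row[o_idx]
            off_called = off[off >= 0]
            p1, p2 = int(row[p_idx[0]]), int(row[p_idx[1]])
            parents_hom_diff = p1 != p2 and p1 in (0, 2) and p2 in (0, 2)
            if parents_hom_diff and maf > 0.1 and het < 0.1:
                usable += len(off_called)
                errors += int((off_called == 1).sum())
            if maf < 0.1:
                minor_is_alt = alt_freq <= 0.5
                if minor_is_alt:
                    errors += int((off_called >= 1).sum())
                else:
                    errors += int((off_called <= 1).sum())
        rows.append({"threshold": thr, "usable_calls": usable, "errors": errors})
    return FamilyQCReport(pd.DataFrame(rows))


def gq_sweep(report_fn, records, samples, parent_ids=("P1", "P2"),
             gq_grid: tuple[int, ...] | None = None) -> FamilyQCReport:
    """Run a family-QC report function over a GQ grid; when no grid is
    given one is derived from the observed GQ deciles."""
    if gq_grid is None:
        gqs = [
            c.gq for r in records for c in r.calls.values() if not c.is_missing
        ]
        if gqs:
            qs = np.unique(np.percentile(gqs, np.arange(0, 100, 10)).astype(int))
            gq_grid = tuple(int(q) for q in qs)
        else:
            gq_grid = DEFAULT_GQ_GRID
    return report_fn(records, samples, parent_ids, gq_grid)
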