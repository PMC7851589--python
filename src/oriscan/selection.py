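"""Per-segment dN, dS and ω by codon counting (Nei–Gojobori 1986).

Rates are estimated per gene segment by the classic counting method:
synonymous and nonsynonymous *sites* are counted per codon as the fraction
of the three possible changes at each position that preserve the amino acid
(changes to stop codons count as nonsynonymous); *differences* between a
codon pair are apportioned by averaging over all shortest mutation paths,
excluding paths that pass through a stop codon.  Proportions are corrected
for multiple hits with the Jukes–Cantor formula d = −(3/4)·ln(1 − 4p/3); a
pair with p ≥ 3/4 is saturated and excluded.  In the low-divergence regime
this analysis targets, counting and ML estimates of dN/dS agree closely.

Multi-taxon segments take the mean over all unordered sequence pairs.
ω = dN/dS is undefined (not infinite) when dS = 0 and such segments are
excluded from the length-weighted genome ω average; outliers are flagged on
ω alone and drag their dN and dS out of every downstream summary with them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .blocks import GeneSegment
from .replicon import Replicon, transform_distances
from .spatial import WINDOW_WIDTHS, flag_outliers
from .regression import RegressionResult, fit_window_linear
import statsmodels.api as sm

logger = logging.getLogger(__name__)

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
BASES = "ACGT"


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


def codon_sites(codon: str) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes producing a stop codon are nonsynonymous.
    Stop codons themselves contribute no sites.
    """
    aa = _CODON_TABLE[codon]
    if aa == "*":
        return 0.0, 0.0
    syn = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if _CODON_TABLE[mutant] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def codon_differences(c1: str, c2: str) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over all orderings of the differing positions (shortest
    mutation paths); paths through stop codons are excluded unless every
    path is blocked, in which case all paths count.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for step, i in enumerate(order):
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            # only intermediate stops block a path; the endpoints are given
            if _CODON_TABLE[nxt] == "*" and step < len(order) - 1:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    syn = nonsyn = 0.0
    for steps in usable:
        for a, b in steps:
            if _CODON_TABLE[a] == _CODON_TABLE[b]:
                syn += 1
            else:
                nonsyn += 1
    n = len(usable)
    return syn / n, nonsyn / n


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = −(3/4)·ln(1 − 4p/3); requires p < 3/4."""
    if p >= 0.75:
        raise ValueError("proportion at or beyond Jukes-Cantor saturation")
    if p <= 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class SelectionRecord:
    segment_id: str
    length_codons: int
    dn: Optional[float]
    ds: Optional[float]
    omega: Optional[float]  # None when dS = 0 (undefined, not infinite)
    distance: Optional[float] = None  # transformed distance of segment midpoint
    saturated: bool = False
    n_pairs: int = 0
    outlier: bool = False

    @property
    def length_bp(self) -> int:
        return 3 * self.length_codons


def pairwise_ng86(seq1: str, seq2: str) -> Optional[Tuple[float, float]]:
    """(dN, dS) for one sequence pair, or None if the pair is saturated."""
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise ValueError("sequences must be equal length and codon-complete")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = codon_differences(c1, c2)
        Sd += sd
        Nd += nd
    if S <= 0 or N <= 0:
        return None
    pS, pN = Sd / S, Nd / N
    if pS >= 0.75 or pN >= 0.75:
        return None
    return jukes_cantor(pN), jukes_cantor(pS)


def compute_dn_ds(
    segment: GeneSegment,
    replicon: Optional[Replicon] = None,
    reference: Optional[str] = None,
) -> SelectionRecord:
    """Segment dN, dS, ω as means over all unordered taxon pairs.

    Saturated pairs are dropped from the means; a segment where every pair
    saturates is flagged and excluded downstream.  The segment's distance is
    the transformed distance of its midpoint in the reference taxon (first
    taxon by default), when a replicon is supplied.
    """
    taxa = segment.taxa
    if len(taxa) < 2:
        raise ValueError(f"segment {segment.id}: need >=2 sequences")
    dns, dss = [], []
    for a, b in combinations(taxa, 2):
        res = pairwise_ng86(segment.seqs[a], segment.seqs[b])
        if res is not None:
            dns.append(res[0])
            dss.append(res[1])
    record = SelectionRecord(
        segment_id=segment.id,
        length_codons=segment.length // 3,
        dn=None, ds=None, omega=None,
        saturated=not dns,
        n_pairs=len(dns),
    )
    if replicon is not None:
        ref = reference or taxa[0]
        pm = segment.position_maps[ref]
        midpoint = int((int(pm.min()) + int(pm.max())) // 2)
        midpoint = min(max(midpoint, 1), replicon.length)
        dist, _ = transform_distances([midpoint], replicon)
        record.distance = float(dist[0])
    if not dns:
        logger.warning("segment %s: all pairs saturated", segment.id)
        return record
    record.dn = float(np.mean(dns))
    record.ds = float(np.mean(dss))
    if record.ds > 0:
        record.omega = record.dn / record.ds
    return record


def omega_outlier_filter(records: Sequence[SelectionRecord], mode: str = "tukey") -> List[SelectionRecord]:
    """Flag records whose ω is a Tukey-fence outlier (in place; returns records).

    Only defined ω values participate; a flagged record's dN and dS are
    excluded from all downstream summaries along with its ω.
    """
    defined = [r for r in records if r.omega is not None]
    if len(defined) >= 4:
        mask = flag_outliers([r.omega for r in defined], mode=mode)
        for r, bad in zip(defined, mask):
            r.outlier = bool(bad)
    return list(records)


def weighted_genome_average(
    records: Sequence[SelectionRecord],
) -> Tuple[Optional[float], Optional[float], Optional[float]]:
    """Length-weighted (dS̄, dN̄, ω̄) over non-outlier, non-saturated records.

    ω̄ additionally excludes records with dS = 0 (undefined ω), mirroring
    the zero rule; dN̄ and dS̄ keep them.
    """
    usable = [r for r in records if not r.outlier and not r.saturated and r.dn is not None]
    if not usable:
        logger.warning("no usable selection records; averages undefined")
        return None, None, None
    w = np.array([r.length_bp for r in usable], dtype=float)
    dn = np.array([r.dn for r in usable])
    ds = np.array([r.ds for r in usable])
    dn_bar = float(np.average(dn, weights=w))
    ds_bar = float(np.average(ds, weights=w))
    with_omega = [r for r in usable if r.omega is not None]
    if with_omega:
        ww = np.array([r.length_bp for r in with_omega], dtype=float)
        om = np.array([r.omega for r in with_omega])
        omega_bar = float(np.average(om, weights=ww))
    else:
        omega_bar = None
    return ds_bar, dn_bar, omega_bar


def fit_selection_regressions(
    records: Sequence[SelectionRecord],
    window_widths: Sequence[int] = WINDOW_WIDTHS,
) -> List[RegressionResult]:
    """OLS of dN, dS and ω on segment-midpoint distance, plus windowed variants."""
    usable = [
        r for r in records
        if not r.outlier and not r.saturated and r.dn is not None and r.distance is not None
    ]
    results: List[RegressionResult] = []
    for response in ("dn", "ds", "omega"):
        pts = [
            (r.distance, getattr(r, response))
            for r in usable
            if getattr(r, response) is not None
        ]
        if len(pts) < 3 or len({d for d, _ in pts}) < 2:
            logger.warning("selection regression for %s skipped: %d usable points", response, len(pts))
            continue
        x = np.array([d for d, _ in pts])
        y = np.array([v for _, v in pts])
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        results.append(
            RegressionResult(
                model="linear",
                coefficient=float(fit.params[1]),
                intercept=float(fit.params[0]),
                se=float(fit.bse[1]),
                p_value=float(fit.pvalues[1]),
                n=int(fit.nobs),
                r_squared=float(fit.rsquared),
                window=None,
                metadata={"response": response},
            )
        )
        # windowed-average variants
        for w in window_widths:
            idx = (x // w).astype(int)
            df = pd.DataFrame({"window": idx, "y": y})
            means = df.groupby("window")["y"].mean()
            if len(means) < 3:
                continue
            win = pd.DataFrame(
                {
                    "window": means.index,
                    "start": means.index * w,
                    "end": (means.index + 1) * w,
                    "density": means.to_numpy(),
                    "outlier": False,
                }
            )
            res = fit_window_linear(win, w, response="density", response_name=response)
            if res is not None:
                res.metadata["response"] = response
                results.append(res)
    return results


def records_to_frame(records: Sequence[SelectionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "segment": r.segment_id,
                "length_bp": r.length_bp,
                "dN": r.dn,
                "dS": r.ds,
                "omega": r.omega,
                "distance": r.distance,
                "saturated": r.saturated,
                "outlier": r.outlier,
                "n_pairs": r.n_pairs,
                "method": "NG86+JC",
            }
            for r in records
        ]
    )
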