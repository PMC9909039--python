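"""Independent brute-force oracles for the descriptor and metric formulas.

Everything here is written as literal, loop-based arithmetic straight from
the defining equations, deliberately sharing no code with the package's
vectorized implementations (only the shipped raw property tables are read,
since those values are data, not computation).
"""

import math

from bitterpep.peptides import STANDARD_RESIDUES
from bitterpep.properties import (
    CODON_COUNTS,
    load_distance_matrix,
    load_scale,
)

RES = STANDARD_RESIDUES

GROUPS = {
    "g1": "GAVLMI", "g2": "FYW", "g3": "KRH", "g4": "DE", "g5": "STCPNQ",
}
GROUP_OF = {r: g for g, members in GROUPS.items() for r in members}


def normalize_oracle(raw: dict) -> dict:
    """Two-pass standard-normal normalization of a residue->value map."""
    mean = sum(raw[r] for r in RES) / 20
    denom = math.sqrt(sum((raw[r] - mean) ** 2 for r in RES) / 20)
    return {r: (raw[r] - mean) / denom for r in RES}


def _scales():
    return tuple(
        normalize_oracle(load_scale(n).as_dict())
        for n in ("hydrophobicity", "hydrophilicity", "side_chain_mass")
    )


def _matrices():
    sw = load_distance_matrix("schneider_wrede_synthetic")
    gr = load_distance_matrix("grantham")
    as_dict = lambda m: {(a, b): m[(a, b)] for a in RES for b in RES}
    return as_dict(sw), as_dict(gr)


H1, H2, M = _scales()
SW, GRANTHAM = _matrices()


def theta_oracle(a: str, b: str) -> float:
    return (
        (H1[a] - H1[b]) ** 2 + (H2[a] - H2[b]) ** 2 + (M[a] - M[b]) ** 2
    ) / 3


def hydro_corr_oracle(a: str, b: str) -> tuple[float, float]:
    return H1[a] * H1[b], H2[a] * H2[b]


def aac_oracle(seq: str) -> dict:
    return {r: seq.count(r) / len(seq) for r in RES}


def tpaac_oracle(seq: str, lam: int = 1, omega: float = 0.05) -> list[float]:
    n = len(seq)
    thetas = []
    for d in range(1, lam + 1):
        thetas.append(
            sum(theta_oracle(seq[i], seq[i + d]) for i in range(n - d)) / (n - d)
        )
    freqs = [seq.count(r) / n for r in RES]
    denom = sum(freqs) + omega * sum(thetas)
    return [f / denom for f in freqs] + [omega * t / denom for t in thetas]


def apaac_oracle(seq: str, lam: int = 1, w: float = 0.5) -> list[float]:
    n = len(seq)
    taus = []
    for d in range(1, lam + 1):
        taus.append(
            sum(H1[seq[i]] * H1[seq[i + d]] for i in range(n - d)) / (n - d)
        )
        taus.append(
            sum(H2[seq[i]] * H2[seq[i + d]] for i in range(n - d)) / (n - d)
        )
    freqs = [seq.count(r) / n for r in RES]
    denom = sum(freqs) + w * sum(taus)
    return [f / denom for f in freqs] + [w * t / denom for t in taus]


def asdc_oracle(seq: str) -> list[float]:
    n = len(seq)
    counts = {(a, b): 0 for a in RES for b in RES}
    for i in range(n):
        for j in range(i + 1, n):
            counts[(seq[i], seq[j])] += 1
    total = n * (n - 1) / 2
    return [counts[(a, b)] / total for a in RES for b in RES]


def dpc_oracle(seq: str) -> list[float]:
    n = len(seq)
    counts = {(a, b): 0 for a in RES for b in RES}
    for i in range(n - 1):
        counts[(seq[i], seq[i + 1])] += 1
    return [counts[(a, b)] / (n - 1) for a in RES for b in RES]


def dde_oracle(seq: str) -> list[float]:
    n = len(seq)
    dc = dpc_oracle(seq)
    out = []
    for k, (a, b) in enumerate((a, b) for a in RES for b in RES):
        tm = (CODON_COUNTS[a] / 61) * (CODON_COUNTS[b] / 61)
        tv = tm * (1 - tm) / (n - 1)
        out.append((dc[k] - tm) / math.sqrt(tv))
    return out


def gaac_oracle(seq: str) -> list[float]:
    return [
        sum(1 for c in seq if GROUP_OF[c] == g) / len(seq)
        for g in ("g1", "g2", "g3", "g4", "g5")
    ]


def gdpc_oracle(seq: str) -> list[float]:
    mapped = "".join(GROUP_OF[c][1] for c in seq)  # 5-letter digit alphabet
    n = len(mapped)
    counts = {(a, b): 0 for a in "12345" for b in "12345"}
    for i in range(n - 1):
        counts[(mapped[i], mapped[i + 1])] += 1
    return [counts[(a, b)] / (n - 1) for a in "12345" for b in "12345"]


def soc_oracle(seq: str, nlag: int = 1) -> list[float]:
    n = len(seq)
    out = []
    for mat in (SW, GRANTHAM):
        for d in range(1, nlag + 1):
            out.append(
                sum(mat[(seq[i], seq[i + d])] ** 2 for i in range(n - d))
            )
    return out


def qso_oracle(seq: str, nlag: int = 1, w: float = 0.1) -> list[float]:
    n = len(seq)
    freqs = [seq.count(r) / n for r in RES]
    out = []
    for mat in (SW, GRANTHAM):
        taus = [
            sum(mat[(seq[i], seq[i + d])] ** 2 for i in range(n - d))
            for d in range(1, nlag + 1)
        ]
        denom = sum(freqs) + w * sum(taus)
        out.extend(f / denom for f in freqs)
        out.extend(w * t / denom for t in taus)
    return out


# --- metric oracles ---------------------------------------------------------


def confusion_oracle(truth, calls):
    tp = sum(1 for t, c in zip(truth, calls) if t == 1 and c == 1)
    fn = sum(1 for t, c in zip(truth, calls) if t == 1 and c == 0)
    tn = sum(1 for t, c in zip(truth, calls) if t == 0 and c == 0)
    fp = sum(1 for t, c in zip(truth, calls) if t == 0 and c == 1)
    return tp, fp, tn, fn


def mcc_oracle(tp, fp, tn, fn):
    denom = math.sqrt(
        (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    if denom == 0:
        return 0.0
    return (tn * tp - fn * fp) / denom


def auroc_pair_oracle(truth, scores):
    """P(random positive outscores random negative), ties counted 1/2."""
    pos = [s for t, s in zip(truth, scores) if t == 1]
    neg = [s for t, s in zip(truth, scores) if t == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
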