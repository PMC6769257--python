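"""Synthetic proteins with planted targeting-peptide grammars.

The generator emits the sequence regularities each class of N-terminal
targeting peptide is known for, so that training, evaluation and the
interpretability analyses are exercisable without any database download:

* **SP** — n-region (1-5 residues, K/R-enriched), hydrophobic h-region
  (7-15 residues from L/A/V/I/F) and a short c-region ending in the
  small-residue "A-X-A" pattern at positions -1 and -3 before the cleavage
  site.
* **mTP** — a 15-60 residue peptide enriched in R, L and S and depleted of
  acidic residues, with an arginine planted at -2, -3 or -10 relative to the
  cleavage site (the three mitochondrial peptidase signatures); the final 12
  peptide positions are otherwise arginine-free so the planted residue is the
  nearest upstream arginine.
* **cTP** — alanine at position 2 with probability ``p_a2`` (default 0.65),
  an S/T-enriched core containing no acidic residues, 30-80 residues long.
* **luTP** — bipartite: a cTP-like stretch followed by an SP-like stretch;
  only the second (thylakoidal processing) cleavage is annotated.
* **noTP** — background composition throughout (uniform by default, keeping
  the chance floor analytic).

Every sequence starts with methionine; a mature region drawn from the
background follows each peptide.  cTP and luTP records are assigned to the
plant group; other classes are mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .sequence_io import ALPHABET, CLASSES, ProteinRecord

_ACIDIC = "DE"
_HYDROPHOBIC = "LAVIF"
_SMALL = "ACGPS"


def _dist(base: float = 1.0, **boost: float) -> np.ndarray:
    """Categorical distribution over ALPHABET: uniform weights scaled by
    per-residue boosts (weight, not probability), then normalised."""
    w = np.full(20, base)
    for aa, val in boost.items():
        w[ALPHABET.index(aa)] = val
    return w / w.sum()


def _deplete(dist: np.ndarray, residues: str, factor: float = 0.0) -> np.ndarray:
    w = dist.copy()
    for aa in residues:
        w[ALPHABET.index(aa)] *= factor
    return w / w.sum()


@dataclass
class SyntheticSpec:
    """Generator conditions; defaults define the package's study conditions."""

    n_per_class: Dict[str, int] = field(
        default_factory=lambda: {"noTP": 250, "SP": 100, "mTP": 75, "cTP": 50, "luTP": 25}
    )
    seed: int = 0
    mature_len_range: Tuple[int, int] = (30, 80)
    notp_len_range: Tuple[int, int] = (50, 160)
    # SP grammar
    sp_n_len: Tuple[int, int] = (1, 5)
    sp_h_len: Tuple[int, int] = (7, 15)
    sp_c_len: Tuple[int, int] = (3, 7)
    sp_kr_weight: float = 8.0
    # mTP grammar
    mtp_len: Tuple[int, int] = (15, 60)
    mtp_arg_offsets: Tuple[int, ...] = (-2, -3, -10)
    mtp_arg_weights: Tuple[float, ...] = (0.40, 0.35, 0.25)
    mtp_rfree_tail: int = 12
    # cTP grammar
    ctp_len: Tuple[int, int] = (30, 80)
    p_a2: float = 0.65
    # luTP grammar
    lutp_ctp_len: Tuple[int, int] = (20, 40)

    def __post_init__(self) -> None:
        for cls, n in self.n_per_class.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r}")
            if n < 0:
                raise ValueError(f"negative count for class {cls}")
        if abs(sum(self.mtp_arg_weights) - 1.0) > 1e-9:
            raise ValueError("mtp_arg_weights must sum to 1")
        if self.mtp_len[0] < -min(self.mtp_arg_offsets) + 1:
            raise ValueError("mTP minimum length cannot accommodate the "
                             "planted arginine offsets")


# per-class residue distributions (module constants so tests can read them)
BACKGROUND = _dist()
SP_N_REGION = _dist(1.0, K=8.0, R=8.0)
SP_C_REGION = _dist(1.0, A=3.0, S=2.0, G=2.0)
MTP_BODY = _deplete(_dist(1.0, R=6.0, L=6.0, S=6.0), _ACIDIC, 0.02)
MTP_TAIL = _deplete(MTP_BODY, "R", 0.0)  # arginine-free near-CS zone
CTP_CORE = _deplete(_dist(1.0, S=7.0, T=7.0), _ACIDIC, 0.0)
CTP_POS2_ALT = _deplete(_dist(1.0, S=3.0, T=3.0, V=2.0), _ACIDIC + "A", 0.0)


def _draw(rng: np.random.Generator, dist: np.ndarray, n: int) -> str:
    return "".join(ALPHABET[i] for i in rng.choice(20, size=n, p=dist))


def _sp_like(rng: np.random.Generator, spec: SyntheticSpec,
             n_len: Optional[Tuple[int, int]] = None) -> str:
    """An SP-style peptide body (without the leading M): n + h + c regions,
    with A planted at -1 and -3."""
    n_lo, n_hi = n_len or spec.sp_n_len
    n_region = _draw(rng, SP_N_REGION, rng.integers(n_lo, n_hi + 1))
    h_region = "".join(rng.choice(list(_HYDROPHOBIC),
                                  size=rng.integers(spec.sp_h_len[0], spec.sp_h_len[1] + 1)))
    c_region = list(_draw(rng, SP_C_REGION, rng.integers(spec.sp_c_len[0], spec.sp_c_len[1] + 1)))
    c_region[-1] = "A"
    c_region[-3] = "A"
    return n_region + h_region + "".join(c_region)


def _make_sp(rng, spec: SyntheticSpec) -> Tuple[str, int]:
    body = _sp_like(rng, spec)
    return "M" + body, 1 + len(body)


def _make_mtp(rng, spec: SyntheticSpec) -> Tuple[str, int]:
    L = int(rng.integers(spec.mtp_len[0], spec.mtp_len[1] + 1))
    offsets = [o for o in spec.mtp_arg_offsets if -o <= L - 1]
    weights = np.array([w for o, w in zip(spec.mtp_arg_offsets, spec.mtp_arg_weights)
                        if -o <= L - 1])
    offset = int(rng.choice(offsets, p=weights / weights.sum()))
    tail = min(spec.mtp_rfree_tail, L - 1)
    body = list("M" + _draw(rng, MTP_BODY, L - 1 - tail) + _draw(rng, MTP_TAIL, tail))
    body[L + offset] = "R"  # position cs + 1 + offset, 0-based = L + offset
    return "".join(body), L


def _ctp_like(rng, spec: SyntheticSpec, length: int) -> str:
    """cTP-style body including the leading M; acid-free, S/T-rich core."""
    pos2 = "A" if rng.random() < spec.p_a2 else _draw(rng, CTP_POS2_ALT, 1)
    return "M" + pos2 + _draw(rng, CTP_CORE, length - 2)


def _make_ctp(rng, spec: SyntheticSpec) -> Tuple[str, int]:
    L = int(rng.integers(spec.ctp_len[0], spec.ctp_len[1] + 1))
    return _ctp_like(rng, spec, L), L


def _make_lutp(rng, spec: SyntheticSpec) -> Tuple[str, int]:
    first = _ctp_like(rng, spec, int(rng.integers(spec.lutp_ctp_len[0],
                                                  spec.lutp_ctp_len[1] + 1)))
    second = _sp_like(rng, spec, n_len=(1, 3))
    seq = first + second
    return seq, len(seq)


def generate(spec: SyntheticSpec) -> List[ProteinRecord]:
    """Generate labelled records; reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    makers = {"SP": _make_sp, "mTP": _make_mtp, "cTP": _make_ctp, "luTP": _make_lutp}
    records: List[ProteinRecord] = []
    counter = 0
    for cls in CLASSES:  # fixed class order keeps output deterministic
        n = spec.n_per_class.get(cls, 0)
        for _ in range(n):
            counter += 1
            rid = f"s{spec.seed}r{counter:05d}_{cls}"  # seed in id: no clashes
                                                       # across generated sets
            if cls == "noTP":
                L = int(rng.integers(spec.notp_len_range[0], spec.notp_len_range[1] + 1))
                seq = "M" + _draw(rng, BACKGROUND, L - 1)
                cs = None
                group = "plant" if rng.random() < 0.5 else "nonplant"
            else:
                peptide, cs = makers[cls](rng, spec)
                mature = _draw(rng, BACKGROUND,
                               int(rng.integers(spec.mature_len_range[0],
                                                spec.mature_len_range[1] + 1)))
                seq = peptide + mature
                group = ("plant" if cls in ("cTP", "luTP")
                         else ("plant" if rng.random() < 0.5 else "nonplant"))
            records.append(ProteinRecord(id=rid, sequence=seq, group=group,
                                         label=cls, cs=cs))
    return records


def generate_family(ancestor: ProteinRecord, n_copies: int, rate: float,
                    seed: int = 0) -> List[ProteinRecord]:
    """Point-substituted homologues of ``ancestor`` (labels and cs kept).

    Each site is replaced with probability ``rate`` by a residue drawn
    uniformly from the 20-letter alphabet (which may equal the original, so
    the expected per-site identity is (1 - rate) + rate/20).
    """
    if not (0.0 < rate < 0.5):
        raise ValueError("substitution rate must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_copies):
        seq = list(ancestor.sequence)
        hits = rng.random(len(seq)) < rate
        for i in np.flatnonzero(hits):
            seq[i] = ALPHABET[rng.integers(20)]
        out.append(replace(ancestor, id=f"{ancestor.id}_fam{k + 1}",
                           sequence="".join(seq)))
    return out
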