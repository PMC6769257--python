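"""Model-introspection analyses: attention profiles, sequence/attention LOGOs,
position-2 composition, arginine-distance distributions and secondary-structure
preference profiles.

Relative positions around the cleavage bond use the convention -1 = last
peptide residue, +1 = first mature residue; there is no position 0.  With the
N-terminus as anchor, offsets are the ordinary 1-based sequence positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import Prediction
from .sequence_io import ALPHABET, CS_CLASSES, RESIDUE_INDEX, ProteinRecord

SMALL_RESIDUES = ("A", "C", "G", "P", "S")  # permit Met excision at position 2


def _offset_to_position(offset: int, anchor: str, cs: Optional[int]) -> int:
    """1-based sequence position of ``offset`` under the given anchor."""
    if anchor == "n_terminus":
        if offset < 1:
            raise ValueError("n-terminus offsets start at 1")
        return offset
    if anchor == "cleavage_site":
        if offset == 0:
            raise ValueError("no position 0 around the cleavage bond")
        if cs is None:
            raise ValueError("cleavage-site anchor requires a cs")
        return cs + offset + 1 if offset < 0 else cs + offset
    raise ValueError(f"unknown anchor {anchor!r}")


@dataclass
class LogoMatrix:
    """Positions x 20 letter-weight matrix with its alignment anchor.

    ``mode="frequency"``: each row with data sums to 1 (residue frequencies).
    ``mode="attention_mass"``: row entries are the mean attention mass carried
    by each residue at that offset; the row sum equals the mean attention
    profile there.  Offsets no record covers are flagged in ``has_data``.
    """

    values: np.ndarray            # (n_offsets, 20)
    offsets: List[int]
    anchor: str                   # "n_terminus" | "cleavage_site"
    mode: str                     # "frequency" | "attention_mass"
    has_data: np.ndarray          # (n_offsets,) bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.offsets, columns=list(ALPHABET))

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("offset").to_csv(path)


def attention_profile(prediction: Prediction) -> np.ndarray:
    """Per-position maximum attention weight across all heads."""
    return prediction.attention.max(axis=0)


def build_logo(records: Sequence[ProteinRecord], anchor: str, offsets: Iterable[int],
               mode: str = "frequency",
               weights: Optional[Dict[str, np.ndarray]] = None,
               cs_override: Optional[Dict[str, int]] = None) -> LogoMatrix:
    """Aggregate residue frequencies or attention mass across aligned records.

    ``weights`` maps record id -> per-position attention profile (required for
    ``mode="attention_mass"``); ``cs_override`` substitutes predicted cleavage
    sites for the annotated ones when anchoring at the cleavage bond.
    """
    offsets = list(offsets)
    if mode not in ("frequency", "attention_mass"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "attention_mass" and weights is None:
        raise ValueError("attention_mass mode needs per-record weight vectors")
    values = np.zeros((len(offsets), 20))
    counts = np.zeros(len(offsets))
    for rec in records:
        cs = cs_override.get(rec.id) if cs_override else rec.cs
        for i, off in enumerate(offsets):
            pos = _offset_to_position(off, anchor, cs)
            if not (1 <= pos <= len(rec.sequence)):
                continue
            aa = rec.sequence[pos - 1]
            j = RESIDUE_INDEX.get(aa)
            if j is None:
                continue
            counts[i] += 1
            if mode == "frequency":
                values[i, j] += 1.0
            else:
                values[i, j] += float(weights[rec.id][pos - 1])
    has_data = counts > 0
    # frequency: normalise to residue frequencies; attention_mass: mean over
    # the records contributing to the offset
    values[has_data] /= counts[has_data, None]
    return LogoMatrix(values=values, offsets=offsets, anchor=anchor, mode=mode,
                      has_data=has_data)


def position2_table(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """Per (class, group): frequency of each small residue at position 2 and
    their sum (the fraction of N-termini whose Met can be excised)."""
    rows = []
    groups: Dict[Tuple[str, str], List[ProteinRecord]] = {}
    for r in records:
        if len(r.sequence) < 2 or r.label is None:
            continue
        groups.setdefault((r.label, r.group), []).append(r)
    for (label, group), recs in sorted(groups.items()):
        freqs = {aa: np.mean([r.sequence[1] == aa for r in recs]) for aa in SMALL_RESIDUES}
        rows.append({"label": label, "group": group, "n": len(recs), **freqs,
                     "cleavable": sum(freqs.values())})
    return pd.DataFrame(rows)


def nearest_upstream_arginine(record: ProteinRecord,
                              cs: Optional[int] = None) -> Optional[int]:
    """Relative position (-1 = last peptide residue) of the arginine closest
    to the cleavage site within the peptide, or None if the peptide has no R.
    """
    cs = cs if cs is not None else record.cs
    if cs is None:
        raise ValueError("record has no cleavage site")
    for pos in range(cs, 0, -1):
        if record.sequence[pos - 1] == "R":
            return pos - (cs + 1)
    return None


def arginine_distance_distribution(records: Sequence[ProteinRecord],
                                   cs_override: Optional[Dict[str, int]] = None
                                   ) -> Dict[int, int]:
    """Histogram of nearest-upstream-arginine offsets (records lacking an
    upstream arginine are skipped)."""
    hist: Dict[int, int] = {}
    for r in records:
        cs = cs_override.get(r.id) if cs_override else r.cs
        if cs is None:
            continue
        d = nearest_upstream_arginine(r, cs)
        if d is not None:
            hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items()))


def load_propensity_scale(path=None) -> pd.DataFrame:
    """Helix/sheet/turn propensities per residue (bundled Chou-Fasman scale by
    default; any TSV with columns residue/helix/sheet/turn may be supplied)."""
    if path is None:
        ref = resources.files("tpsort") / "data" / "propensity_chou_fasman.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return df.set_index("residue")


def structure_preference_profile(records: Sequence[ProteinRecord],
                                 scale: pd.DataFrame, anchor: str,
                                 offsets: Iterable[int],
                                 cs_override: Optional[Dict[str, int]] = None
                                 ) -> pd.DataFrame:
    """log2 of the mean structure propensity of the residues at each offset.

    Returns a DataFrame indexed by offset with one column per structure class;
    offsets with no data hold NaN.
    """
    offsets = list(offsets)
    out = pd.DataFrame(index=pd.Index(offsets, name="offset"),
                       columns=scale.columns, dtype=float)
    for off in offsets:
        vals: Dict[str, List[float]] = {c: [] for c in scale.columns}
        for rec in records:
            cs = cs_override.get(rec.id) if cs_override else rec.cs
            try:
                pos = _offset_to_position(off, anchor, cs)
            except ValueError:
                continue
            if not (1 <= pos <= len(rec.sequence)):
                continue
            aa = rec.sequence[pos - 1]
            if aa not in scale.index:
                continue
            for c in scale.columns:
                vals[c].append(float(scale.loc[aa, c]))
        for c in scale.columns:
            if vals[c]:
                out.loc[off, c] = np.log2(np.mean(vals[c]))
    return out
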