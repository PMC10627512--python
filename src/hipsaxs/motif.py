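"""Gly-rich-loop phosphosite motif classification for Hip-family kinases.

HipT-like serine/threonine kinases carry two candidate auto-phosphorylation
sites in the Gly-rich loop, separated by one small aliphatic residue
(psi = Ile/Leu/Val): the wild-type E. coli O127:H6 HipT window is S-I-S.
Orthologues fall into motif groups defined by the two flank positions:
SpsiS, (S/T)psiT, (S/T)psiP, SpsiQ and psipsiT, with everything else
(including windows without an aliphatic center) collected as "other".
This module classifies three-residue phospho windows, locates the window in
full loop sequences, and tabulates per-position residue frequencies for
consensus/logo construction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("hipsaxs")

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS = set("XBZJUO")
PSI = set("ILV")  # small aliphatic center

GROUP_SPSIS = "SpsiS"
GROUP_ST_PSI_T = "(S/T)psiT"
GROUP_ST_PSI_P = "(S/T)psiP"
GROUP_SPSIQ = "SpsiQ"
GROUP_PSIPSIT = "psipsiT"
GROUP_OTHER = "other"

#: All labels, in classification precedence order (SpsiS, the dominant
#: class, is matched first; T-flank TpsiT/TpsiP windows fall under the
#: (S/T) groups).
GROUPS = (GROUP_SPSIS, GROUP_ST_PSI_T, GROUP_ST_PSI_P, GROUP_SPSIQ,
          GROUP_PSIPSIT, GROUP_OTHER)

#: Default phospho-window anchor: a triplet with an aliphatic center,
#: followed by a glycine within the next two residues (the Gly-rich
#: stretch of the loop).  Override with explicit coordinates when the
#: window is known from an alignment.
DEFAULT_WINDOW_PATTERN = r"(?=([A-Z][ILV][A-Z])[A-Z]?G)"


class MotifError(ValueError):
    pass


def classify_motif(triplet: str) -> str:
    """Classify a three-residue phospho window into its motif group.

    The center must be aliphatic (I/L/V) for any named group; the flanks
    are matched in precedence order SpsiS -> (S/T)psiT -> (S/T)psiP ->
    SpsiQ -> psipsiT -> other.  Ambiguity codes (X/B/Z/...) classify as
    "other" with a warning; letters outside the amino-acid alphabet raise.
    """
    t = triplet.upper()
    if len(t) != 3:
        raise MotifError(f"phospho window must be 3 residues, got {triplet!r}")
    bad = set(t) - AMINO_ACIDS - AMBIGUOUS
    if bad:
        raise MotifError(f"invalid residue letter(s) {sorted(bad)} in {triplet!r}")
    if set(t) & AMBIGUOUS:
        logger.warning("ambiguity code in window %r; classified as other", triplet)
        return GROUP_OTHER
    a, c, b = t
    if c not in PSI:
        return GROUP_OTHER
    if a == "S" and b == "S":
        return GROUP_SPSIS
    if a in "ST" and b == "T":
        return GROUP_ST_PSI_T
    if a in "ST" and b == "P":
        return GROUP_ST_PSI_P
    if a == "S" and b == "Q":
        return GROUP_SPSIQ
    if a in PSI and b == "T":
        return GROUP_PSIPSIT
    return GROUP_OTHER


@dataclass(frozen=True)
class WindowLocator:
    """Where to find the phospho window: explicit 0-based ``start`` (window
    is ``[start, start+3)``) or a regex ``pattern`` whose first capture
    group is the window."""
    start: int | None = None
    pattern: str = DEFAULT_WINDOW_PATTERN

    def locate(self, sequence: str) -> str | None:
        seq = sequence.upper()
        if self.start is not None:
            if self.start < 0 or self.start + 3 > len(seq):
                return None
            return seq[self.start:self.start + 3]
        m = re.search(self.pattern, seq)
        return m.group(1) if m else None


def classify_fasta(source, locator: WindowLocator | None = None) -> pd.DataFrame:
    """Classify every record of a FASTA file/handle.

    Returns a DataFrame with columns ``id``, ``triplet``, ``group``,
    ``located``; records whose window cannot be found are flagged
    (``located=False``, group "other"), never dropped.
    """
    locator = locator or WindowLocator()
    records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise MotifError("empty FASTA input")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise MotifError(f"duplicate record ids: {dupes}")
    rows = []
    for rec in records:
        triplet = locator.locate(str(rec.seq))
        if triplet is None:
            logger.warning("window not located in record %s", rec.id)
            rows.append({"id": rec.id, "triplet": None,
                         "group": GROUP_OTHER, "located": False})
        else:
            rows.append({"id": rec.id, "triplet": triplet,
                         "group": classify_motif(triplet), "located": True})
    return pd.DataFrame(rows, columns=["id", "triplet", "group", "located"])


def consensus_counts(table: pd.DataFrame, normalize: bool = False) -> pd.DataFrame:
    """Per-position residue counts (or frequencies) over the located
    windows; columns are window positions, rows residues.  Frequencies sum
    to 1 at every position; suitable for sequence-logo rendering."""
    located = table[table["located"]] if "located" in table else table
    triplets = [t for t in located["triplet"] if t]
    if not triplets:
        raise MotifError("no located windows to tabulate")
    width = len(triplets[0])
    counts = pd.DataFrame(
        0, index=sorted(AMINO_ACIDS), columns=list(range(width)), dtype=float)
    for t in triplets:
        for pos, aa in enumerate(t):
            counts.loc[aa, pos] += 1
    if normalize:
        counts = counts / counts.sum(axis=0)
    return counts
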