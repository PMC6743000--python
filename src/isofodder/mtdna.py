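"""Taxon assignment of short mitochondrial cytochrome-b (MT-CYB) fragments.

Fragmented sheep/goat remains from Inner Asian sites cannot be reliably
separated from wild congeners (argali, urial, Siberian ibex, markhor) on
morphology alone.  A 110-bp MT-CYB amplicon carries enough diagnostic sites
to make the call: after trimming the PCR primers, each query is compared to a
labelled haplotype panel by Hamming distance over the equal-length amplified
region (no indels are expected in this short conserved fragment, so no gapped
alignment is attempted).  ``N`` bases are mismatch-neutral — conservative for
degraded ancient DNA.  Panel entries carry taxon and domestication-status
labels, so an assignment immediately yields the domestic/wild call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "FORWARD_PRIMER",
    "REVERSE_PRIMER",
    "PanelEntry",
    "HaplotypePanel",
    "AssignmentResult",
    "PrimerNotFoundError",
    "hamming_distance",
    "trim_primers",
    "assign_taxon",
    "HaplotypeClassifier",
]

# PCR primer pair amplifying the 110-bp MT-CYB fragment (CapFC1 / CapRB1b).
FORWARD_PRIMER = "CTCTGTAACTCACATTTGTC"
REVERSE_PRIMER = "GTTTCATGTTTCTAGAAAGGT"


class PrimerNotFoundError(ValueError):
    """A primer could not be located within the allowed mismatch budget."""


@dataclass(frozen=True)
class PanelEntry:
    id: str
    sequence: str
    taxon: str
    status: str  # "domestic" | "wild"


@dataclass
class AssignmentResult:
    """Best-taxon call for one query fragment."""

    query_id: str
    taxon: str
    status: str
    mismatches: int
    margin: int  # distance gap to the closest entry of a different taxon
    ambiguous: bool  # equal minimal distance across distinct taxa
    identical: bool  # exact (0-mismatch) match to a panel entry


def _clean(seq: str) -> str:
    return str(seq).strip().upper().replace("U", "T")


def hamming_distance(a: str, b: str, n_neutral: bool = True) -> int:
    """Mismatch count between equal-length sequences.

    With `n_neutral` (the default) positions where either base is ``N`` do
    not count as mismatches.
    """
    if len(a) != len(b):
        raise ValueError("length_mismatch")
    arr_a = np.frombuffer(_clean(a).encode(), dtype="S1")
    arr_b = np.frombuffer(_clean(b).encode(), dtype="S1")
    diff = arr_a != arr_b
    if n_neutral:
        diff &= (arr_a != b"N") & (arr_b != b"N")
    return int(diff.sum())


def _best_window(read: str, probe: str, n_neutral: bool = True):
    """Sliding-window search; returns (best start, best mismatch count)."""
    k = len(probe)
    if len(read) < k:
        return None, k + 1
    best_start, best_mm = None, k + 1
    for start in range(len(read) - k + 1):
        mm = hamming_distance(read[start : start + k], probe, n_neutral=n_neutral)
        if mm < best_mm:
            best_start, best_mm = start, mm
            if mm == 0:
                break
    return best_start, best_mm


def trim_primers(
    read: str,
    forward: str = FORWARD_PRIMER,
    reverse: str = REVERSE_PRIMER,
    max_mismatch: int = 1,
) -> str:
    """Strip the primer pair from an amplicon read, returning the insert.

    Locates `forward` and the reverse complement of `reverse`, each allowing
    up to `max_mismatch` substitutions; if that fails the reverse-complement
    orientation of the whole read is tried before raising
    :class:`PrimerNotFoundError`.
    """
    read = _clean(read)
    forward = _clean(forward)
    rev_rc = str(Seq(_clean(reverse)).reverse_complement())
    if len(read) <= len(forward) + len(rev_rc):
        raise PrimerNotFoundError("primer_not_found: read shorter than primers")
    for oriented in (read, str(Seq(read).reverse_complement())):
        f_start, f_mm = _best_window(oriented, forward)
        if f_mm > max_mismatch:
            continue
        insert_from = f_start + len(forward)
        r_start, r_mm = _best_window(oriented[insert_from:], rev_rc)
        if r_mm > max_mismatch:
            continue
        return oriented[insert_from : insert_from + r_start]
    raise PrimerNotFoundError("primer_not_found")


class HaplotypePanel:
    """Labelled reference haplotypes over the trimmed amplified region."""

    def __init__(self, entries):
        self.entries = [
            e if isinstance(e, PanelEntry) else PanelEntry(*e) for e in entries
        ]
        if not self.entries:
            raise ValueError("empty haplotype panel")
        lengths = {len(e.sequence) for e in self.entries}
        if len(lengths) != 1:
            raise ValueError(f"panel sequences differ in length: {sorted(lengths)}")
        self.length = lengths.pop()
        for e in self.entries:
            if not e.taxon:
                raise ValueError(f"panel entry {e.id!r} lacks a taxon label")

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_fasta(cls, path) -> "HaplotypePanel":
        """Read a panel FASTA with ``taxon=`` and ``status=`` header tags.

        Example header: ``>hap1 taxon=Ovis_aries status=domestic``.
        Underscores in the taxon tag are read as spaces (FASTA headers are
        whitespace-delimited).
        """
        entries = []
        for record in SeqIO.parse(str(path), "fasta"):
            tags = dict(
                part.split("=", 1)
                for part in record.description.split()
                if "=" in part
            )
            entries.append(
                PanelEntry(
                    id=record.id,
                    sequence=_clean(str(record.seq)),
                    taxon=tags.get("taxon", "").replace("_", " "),
                    status=tags.get("status", "unknown"),
                )
            )
        return cls(entries)

    def to_fasta(self, path):
        with open(path, "w") as fh:
            for e in self.entries:
                taxon = e.taxon.replace(" ", "_")
                fh.write(f">{e.id} taxon={taxon} status={e.status}\n{e.sequence}\n")


def assign_taxon(
    query: str, panel: HaplotypePanel, query_id: str = "query"
) -> AssignmentResult:
    """Nearest-haplotype taxon call for a trimmed query fragment.

    Hamming distance to every panel entry; the minimal-distance taxon wins.
    The margin is the distance gap to the best entry of any *other* taxon;
    a zero margin across distinct taxa marks the call ambiguous.
    """
    query = _clean(query)
    if len(query) != panel.length:
        raise ValueError(
            f"length_mismatch: query {len(query)} != panel {panel.length}"
        )
    dists = np.array(
        [hamming_distance(query, e.sequence) for e in panel.entries], dtype=int
    )
    best_idx = int(np.argmin(dists))
    best = panel.entries[best_idx]
    best_d = int(dists[best_idx])
    other = [d for d, e in zip(dists, panel.entries) if e.taxon != best.taxon]
    margin = int(min(other) - best_d) if other else int(panel.length - best_d)
    return AssignmentResult(
        query_id=query_id,
        taxon=best.taxon,
        status=best.status,
        mismatches=best_d,
        margin=max(margin, 0),
        ambiguous=bool(other) and margin == 0,
        identical=best_d == 0,
    )


class HaplotypeClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-haplotype classifier with optional primer trimming.

    ``fit`` memorises the panel (sequences + taxon labels, optionally
    domestication status); ``predict`` returns the taxon per query.  The
    full per-query detail (mismatches, margin, ambiguity, status) comes from
    :meth:`assign`.

    Parameters
    ----------
    trim : bool, default False
        Trim the PCR primers from queries before comparison.
    max_primer_mismatch : int, default 1
    """

    def __init__(
        self,
        trim=False,
        forward_primer=FORWARD_PRIMER,
        reverse_primer=REVERSE_PRIMER,
        max_primer_mismatch=1,
    ):
        self.trim = trim
        self.forward_primer = forward_primer
        self.reverse_primer = reverse_primer
        self.max_primer_mismatch = max_primer_mismatch

    def fit(self, X, y, status=None):
        """Memorise the panel: `X` sequences, `y` taxon labels."""
        seqs = [str(s) for s in X]
        taxa = [str(t) for t in y]
        if len(seqs) != len(taxa):
            raise ValueError("X and y differ in length")
        if status is None:
            status = ["unknown"] * len(seqs)
        self.panel_ = HaplotypePanel(
            [
                PanelEntry(id=f"ref{i}", sequence=_clean(s), taxon=t, status=st)
                for i, (s, t, st) in enumerate(zip(seqs, taxa, status))
            ]
        )
        self.classes_ = np.unique(taxa)
        return self

    def _prepare(self, seq: str) -> str:
        if self.trim:
            return trim_primers(
                seq,
                forward=self.forward_primer,
                reverse=self.reverse_primer,
                max_mismatch=self.max_primer_mismatch,
            )
        return _clean(seq)

    def assign(self, X, ids=None) -> pd.DataFrame:
        """Detailed assignments as a table (one row per query)."""
        if ids is None:
            ids = [f"q{i}" for i in range(len(X))]
        rows = []
        for qid, seq in zip(ids, X):
            res = assign_taxon(self._prepare(seq), self.panel_, query_id=qid)
            rows.append(vars(res))
        return pd.DataFrame(rows)

    def predict(self, X):
        return self.assign(X)["taxon"].to_numpy()
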