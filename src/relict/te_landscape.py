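"""Kimura 2-parameter repeat divergence landscapes.

The age structure of transposable-element activity is read from the
distance of each annotated TE copy to its family consensus: recently
active families have copies nearly identical to the consensus, old bursts
sit at high divergence. Distances use the Kimura two-parameter (K80)
model, which corrects transitions (proportion P) and transversions (Q)
separately:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Copies are binned by distance into 1% bins up to the 50% detection horizon
(more divergent copies cannot reliably be annotated as repeats at all) and
weighted by aligned copy length, giving the classic repeat landscape:
genome fraction per divergence bin per TE class.

The same ``k2p`` function is used for species divergences
(:mod:`relict.divergence_clock`), which is what makes TE copy ages and
species split depths directly comparable.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

__all__ = [
    "K2PResult",
    "SaturationError",
    "TECopyRecord",
    "k2p",
    "classify_family",
    "parse_align",
    "parse_te_tsv",
    "write_te_tsv",
    "attach_k2p",
    "build_landscape",
    "correlate_te_size",
    "TE_CLASSES",
]

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA", "RC", "Unknown", "Other")

# RepeatMasker-style labels that are repeats but not transposable elements;
# they are tallied separately and excluded from TE landscapes.
_OTHER_LABELS = {
    "SIMPLE_REPEAT", "SIMPLE", "SATELLITE", "LOW_COMPLEXITY",
    "RRNA", "TRNA", "SNRNA", "SCRNA", "SRPRNA", "RNA",
}

N_BINS = 50          # 1% divergence bins covering [0, 0.5)
MAX_DIVERGENCE = 0.5


class SaturationError(ValueError):
    """K80 distance undefined: substitutions are saturated (log of <= 0)."""


@dataclass(frozen=True, slots=True)
class K2PResult:
    P: float        # transition proportion
    Q: float        # transversion proportion
    n_sites: int    # compared (gap/ambiguity-free) columns
    d: float        # K80 distance


@dataclass(slots=True)
class TECopyRecord:
    """One annotated TE copy with its copy-vs-consensus alignment."""

    copy_id: str
    family: str
    te_class: str
    contig: str
    start: int      # 0-based half-open genomic span
    end: int
    copy_seq: str | None = None
    cons_seq: str | None = None
    k2p_result: K2PResult | None = None
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("TE copy span must satisfy end > start")
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")

    @property
    def aligned_copy_bp(self) -> int:
        """Non-gap copy bases when the alignment is present, else the span."""
        if self.copy_seq is not None:
            return sum(1 for c in self.copy_seq if c != "-")
        return self.end - self.start


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


def k2p(seq_a: str, seq_b: str) -> K2PResult:
    """Kimura two-parameter distance between two aligned sequences.

    Columns containing a gap or ambiguity code in either sequence are
    skipped. Raises ``ValueError`` when no columns are comparable and
    :class:`SaturationError` when ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    valid_a = np.isin(a, (b"A", b"C", b"G", b"T"))
    valid_b = np.isin(b, (b"A", b"C", b"G", b"T"))
    valid = valid_a & valid_b
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable (gap/ambiguity-free) columns")
    av, bv = a[valid], b[valid]
    diff = av != bv
    purine_a = (av == b"A") | (av == b"G")
    purine_b = (bv == b"A") | (bv == b"G")
    transitions = int((diff & (purine_a == purine_b)).sum())
    transversions = int(diff.sum()) - transitions
    P = transitions / n
    Q = transversions / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"saturated pair: P={P:.3f}, Q={Q:.3f}")
    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return K2PResult(P=P, Q=Q, n_sites=n, d=float(d))


def classify_family(family: str) -> str:
    """Map a RepeatMasker-style family string to the closed class vocabulary.

    ``rnd-1_family-12#LINE/L2`` -> ``LINE``; simple repeats, satellites and
    structural RNAs map to ``Other``; anything unrecognized is ``Unknown``.
    """
    label = family.split("#")[-1] if "#" in family else family
    label = label.split("/")[0].strip()
    upper = label.upper()
    if upper in ("LINE", "SINE", "LTR", "DNA", "RC"):
        return upper
    if upper in ("ROLLING-CIRCLE", "HELITRON"):
        return "RC"
    if upper in _OTHER_LABELS:
        return "Other"
    return "Unknown"


# Header of an alignment block (documented .align dialect subset):
# score pct_div pct_del pct_ins query qstart qend (qleft) [C] family#class
# cstart cend (cleft) copy_id
_ALIGN_HEADER = re.compile(
    r"^\s*(\d+)\s+([\d.]+)\s+([\d.]+)\s+([\d.]+)\s+(\S+)\s+(\d+)\s+(\d+)\s+"
    r"\((\d+)\)\s+(?:(C)\s+)?(\S+)\s+"
)
_ALIGN_SEQLINE = re.compile(r"^\s*C?\s*(\S+)\s+(\d+)\s+([A-Za-z\-]+)\s+(\d+)\s*$")


def parse_align(path) -> tuple[list[TECopyRecord], int]:
    """Parse a RepeatMasker-style ``.align`` file (documented subset).

    Each block is a header line followed by alternating aligned-sequence
    lines (query first, consensus second, possibly chunked), terminated by
    a blank line or the next header. ``Matrix``/``Kimura``/``Gap`` trailer
    lines are ignored. Malformed blocks are skipped and counted; the count
    is returned alongside the records.
    """
    records: list[TECopyRecord] = []
    n_skipped = 0
    current: dict | None = None

    def _close(block: dict | None) -> None:
        nonlocal n_skipped
        if block is None:
            return
        try:
            copy_seq = "".join(block["query_chunks"])
            cons_seq = "".join(block["cons_chunks"])
            if not copy_seq or len(copy_seq) != len(cons_seq):
                raise ValueError("unpaired or empty aligned sequences")
            records.append(
                TECopyRecord(
                    copy_id=block["copy_id"],
                    family=block["family"],
                    te_class=classify_family(block["family"]),
                    contig=block["contig"],
                    start=block["qstart"] - 1,   # 1-based inclusive -> 0-based half-open
                    end=block["qend"],
                    copy_seq=copy_seq,
                    cons_seq=cons_seq,
                )
            )
        except (ValueError, KeyError) as exc:
            n_skipped += 1
            logger.warning("skipping malformed alignment block: %s", exc)

    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            header = _ALIGN_HEADER.match(line)
            if header and not _ALIGN_SEQLINE.match(line):
                _close(current)
                rest = line[header.end():].split()
                current = {
                    "contig": header.group(5),
                    "qstart": int(header.group(6)),
                    "qend": int(header.group(7)),
                    "family": header.group(10),
                    "copy_id": rest[-1] if rest else f"copy_{len(records) + n_skipped + 1}",
                    "query_chunks": [],
                    "cons_chunks": [],
                }
                continue
            if not stripped:
                continue
            if stripped.startswith(("Matrix", "Kimura", "Gap_init", "Transitions")):
                continue
            seqline = _ALIGN_SEQLINE.match(line)
            if seqline and current is not None:
                name, seq = seqline.group(1), seqline.group(3)
                if name == current["contig"]:
                    current["query_chunks"].append(seq)
                else:
                    current["cons_chunks"].append(seq)
    _close(current)
    return records, n_skipped


_TSV_COLUMNS = ["copy_id", "family", "te_class", "contig", "start", "end", "copy_seq", "cons_seq"]


def parse_te_tsv(path) -> tuple[list[TECopyRecord], int]:
    """TSV fallback for copy-vs-consensus alignments (one row per copy)."""
    df = pd.read_csv(path, sep="\t")
    records: list[TECopyRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        try:
            records.append(
                TECopyRecord(
                    copy_id=str(row.copy_id),
                    family=str(row.family),
                    te_class=str(getattr(row, "te_class", "")) or classify_family(str(row.family)),
                    contig=str(row.contig),
                    start=int(row.start),
                    end=int(row.end),
                    copy_seq=str(row.copy_seq),
                    cons_seq=str(row.cons_seq),
                )
            )
        except (ValueError, TypeError) as exc:
            n_skipped += 1
            logger.warning("skipping malformed TSV row: %s", exc)
    return records, n_skipped


def write_te_tsv(records: Sequence[TECopyRecord], path) -> None:
    pd.DataFrame(
        [
            (r.copy_id, r.family, r.te_class, r.contig, r.start, r.end, r.copy_seq, r.cons_seq)
            for r in records
        ],
        columns=_TSV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def attach_k2p(records: Iterable[TECopyRecord]) -> list[TECopyRecord]:
    """Compute the copy-vs-consensus K80 distance for every record.

    Saturated copies are flagged (never silently dropped); they end up in
    the landscape's unscorable bucket.
    """
    out = []
    for rec in records:
        if rec.copy_seq is None or rec.cons_seq is None:
            rec.saturated = True
        else:
            try:
                rec.k2p_result = k2p(rec.copy_seq, rec.cons_seq)
            except SaturationError:
                rec.saturated = True
            except ValueError:
                rec.saturated = True
        out.append(rec)
    return out


def build_landscape(
    records: Sequence[TECopyRecord], assembly_size: int
) -> tuple[pd.DataFrame, dict]:
    """Bin TE copies into 1% divergence bins weighted by aligned copy bp.

    Returns the landscape table (te_class, bin_low, bin_high, bp,
    genome_fraction) and a summary with per-class totals, the overflow
    bucket (d >= 0.5, beyond the detection horizon), the unscorable bucket
    (saturated / unalignable copies) and the non-TE "Other" tally. The bp
    conservation invariant holds: binned + overflow + unscorable + other
    equals the total copy bp.
    """
    if assembly_size <= 0:
        raise ValueError("assembly_size must be positive")
    bins: dict[tuple[str, int], int] = {}
    overflow_bp = 0
    unscorable_bp = 0
    other_bp = 0
    class_totals: dict[str, int] = {c: 0 for c in TE_CLASSES}
    for rec in records:
        bp = rec.aligned_copy_bp
        class_totals[rec.te_class] = class_totals.get(rec.te_class, 0) + bp
        if rec.te_class == "Other":
            other_bp += bp
            continue
        if rec.k2p_result is None:
            unscorable_bp += bp
            continue
        d = rec.k2p_result.d
        if d >= MAX_DIVERGENCE:
            overflow_bp += bp
            continue
        key = (rec.te_class, int(d * 100))
        bins[key] = bins.get(key, 0) + bp
    rows = [
        {
            "te_class": cls,
            "bin_low": i / 100.0,
            "bin_high": (i + 1) / 100.0,
            "bp": bp,
            "genome_fraction": bp / assembly_size,
        }
        for (cls, i), bp in sorted(bins.items())
    ]
    table = pd.DataFrame(
        rows, columns=["te_class", "bin_low", "bin_high", "bp", "genome_fraction"]
    )
    total_te_bp = sum(v for c, v in class_totals.items() if c != "Other")
    summary = {
        "class_totals_bp": class_totals,
        "total_te_bp": total_te_bp,
        "te_fraction": total_te_bp / assembly_size,
        "overflow_bp": overflow_bp,
        "unscorable_bp": unscorable_bp,
        "other_bp": other_bp,
        "assembly_size": assembly_size,
    }
    return table, summary


def _shared_path_matrix(tree, species: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance: root-to-MRCA shared path length per pair."""
    import dendropy

    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    idx = {sp: i for i, sp in enumerate(species)}
    tips = {t.label for t in tree.taxon_namespace if t.label is not None}
    missing = set(species) - tips
    if missing:
        raise ValueError(f"species absent from tree: {sorted(missing)}")
    n = len(species)
    C = np.zeros((n, n))
    depth: dict[int, float] = {}
    leafset: dict[int, list[int]] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[id(parent)] + (node.edge.length or 0.0)
        depth[id(node)] = d
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            leafset[id(node)] = [idx[label]] if label in idx else []
            if label in idx:
                C[idx[label], idx[label]] = depth[id(node)]
        else:
            children = node.child_nodes()
            sets = [leafset[id(c)] for c in children]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i in sets[a]:
                        for j in sets[b]:
                            C[i, j] = C[j, i] = depth[id(node)]
            leafset[id(node)] = [i for s in sets for i in s]
    return C


def correlate_te_size(data: pd.DataFrame, tree=None) -> dict:
    """Correlate per-species TE content with assembly size.

    ``data`` needs columns species / assembly_size / te_bp. Returns the
    ordinary Pearson correlation and, when a tree is given, the slope and
    correlation of a phylogenetic generalized least squares (PGLS) fit
    under a Brownian-motion covariance (shared root-to-MRCA branch
    lengths). On a star tree with equal tip lengths PGLS reduces to OLS.
    """
    if len(data) < 3:
        raise ValueError("need at least 3 species")
    x = data["assembly_size"].to_numpy(dtype=float)
    y = data["te_bp"].to_numpy(dtype=float)
    r, p = scipy.stats.pearsonr(x, y)
    result = {"pearson_r": float(r), "pearson_p": float(p)}
    if tree is not None:
        species = [str(s) for s in data["species"]]
        C = _shared_path_matrix(tree, species)
        Cinv = np.linalg.inv(C)
        X = np.column_stack([np.ones_like(x), x])
        XtCinv = X.T @ Cinv
        beta = np.linalg.solve(XtCinv @ X, XtCinv @ y)
        resid = y - X @ beta
        rss = float(resid @ Cinv @ resid)
        ones = np.ones_like(y)
        mu = float((ones @ Cinv @ y) / (ones @ Cinv @ ones))
        yc = y - mu
        tss = float(yc @ Cinv @ yc)
        r2 = 1.0 - rss / tss if tss > 0 else float("nan")
        result["pgls_slope"] = float(beta[1])
        result["pgls_intercept"] = float(beta[0])
        result["pgls_r"] = float(np.sign(beta[1]) * np.sqrt(max(r2, 0.0)))
    return result
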