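"""Evaluation machinery: generated-word categorization, AUC, molecular
fingerprints and Tanimoto similarity, binned TC maps, similarity networks,
and nearest-neighbor target identification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import IntEnum

import networkx as nx
import numpy as np
from rdkit import Chem
from scipy.stats import rankdata

from .words import words_share_elements

logger = logging.getLogger("bindtext")

FINGERPRINT_WIDTH = 1024
FINGERPRINT_DEPTH = 6


class CategoryLabel(IntEnum):
    """Four-way categorization of a generated word against the original
    sentence: exact next word, seen elsewhere, element-level variant, new."""

    QUERY_ADJACENT = 1
    EXISTS_IN_ORIGINAL = 2
    VARIATION_OF_EXISTING = 3
    COMPLETELY_NEW = 4


def categorize_word(generated: str, prompt_words: list[str],
                    original_words: list[str]) -> CategoryLabel:
    """Assign the generated word to exactly one category, checked in priority
    order 1 -> 2 -> 3 -> 4:

    1. it equals the word immediately following the prompt;
    2. it appears anywhere else in the original word list;
    3. it shares all element/atom fields with some original word (only the
       numeric prefix differs);
    4. none of the above.

    ``prompt_words`` must be a strict prefix of ``original_words``."""
    generated = str(generated)
    prompt_words = [str(w) for w in prompt_words]
    original_words = [str(w) for w in original_words]
    k = len(prompt_words)
    if k >= len(original_words) or original_words[:k] != prompt_words:
        raise ValueError("prompt must be a strict prefix of the original word list")
    if generated == original_words[k]:
        return CategoryLabel.QUERY_ADJACENT
    if generated in original_words:
        return CategoryLabel.EXISTS_IN_ORIGINAL
    try:
        if any(words_share_elements(generated, w) for w in original_words):
            return CategoryLabel.VARIATION_OF_EXISTING
    except ValueError:
        pass   # unparseable generation cannot be an element-level variant
    return CategoryLabel.COMPLETELY_NEW


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc_from_scores(scores, truth) -> float:
    """Mann-Whitney AUC: probability that a random positive outscores a
    random negative, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# fingerprints and Tanimoto
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fingerprint:
    """Hashed linear-path fingerprint of a molecule, as a set of on-bits."""

    bits: frozenset[int]
    width: int
    smiles: str = ""


def fingerprint_from_smiles(smiles: str, width: int = FINGERPRINT_WIDTH,
                            depth: int = FINGERPRINT_DEPTH) -> Fingerprint:
    """Path-based hashed fingerprint over heavy-atom paths up to ``depth``
    bonds, folded to ``width`` bits.  Canonicalization makes equivalent
    SMILES spellings yield identical fingerprints."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    fp = Chem.RDKFingerprint(mol, minPath=1, maxPath=depth, fpSize=width)
    return Fingerprint(bits=frozenset(int(b) for b in fp.GetOnBits()),
                       width=width, smiles=smiles)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a AND b| / |a OR b|; two empty fingerprints give 0 with a warning."""
    if a.width != b.width:
        raise ValueError("fingerprint widths differ")
    union = a.bits | b.bits
    if not union:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0")
        return 0.0
    return len(a.bits & b.bits) / len(union)


# ---------------------------------------------------------------------------
# TC maps and similarity networks over the 2-D embedding
# ---------------------------------------------------------------------------

def binned_tc_map(coords2d: np.ndarray, tc: np.ndarray,
                  n_bins: int | tuple[int, int] = 100):
    """Partition the embedding bounding box into a grid (100 bins = 10 x 10),
    average the TC values per bin (empty bins are NaN), and return the grid
    plus the per-column and per-row marginal profiles."""
    coords2d = np.asarray(coords2d, dtype=float)
    tc = np.asarray(tc, dtype=float)
    if coords2d.shape[0] == 0:
        raise ValueError("no points to bin")
    if isinstance(n_bins, tuple):
        rows, cols = n_bins
    else:
        side = int(round(np.sqrt(n_bins)))
        if side * side != n_bins:
            raise ValueError("n_bins must be a perfect square or an explicit (rows, cols)")
        rows = cols = side
    x, y = coords2d[:, 0], coords2d[:, 1]

    def _bin(vals, k):
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            return np.zeros(vals.size, dtype=int)
        idx = np.floor((vals - lo) / (hi - lo) * k).astype(int)
        return np.clip(idx, 0, k - 1)

    ci, ri = _bin(x, cols), _bin(y, rows)
    grid = np.full((rows, cols), np.nan)
    for r in range(rows):
        for c in range(cols):
            in_bin = (ri == r) & (ci == c)
            if in_bin.any():
                grid[r, c] = tc[in_bin].mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_profile = np.nanmean(grid, axis=0)
        row_profile = np.nanmean(grid, axis=1)
    return grid, col_profile, row_profile


def similarity_network(query_idx: int, coords2d: np.ndarray,
                       smiles_per_row: list[str | None], k: int = 20,
                       n_edges: int = 10, width: int = FINGERPRINT_WIDTH,
                       depth: int = FINGERPRINT_DEPTH) -> nx.Graph:
    """Select the ``k`` rows nearest the query in the 2-D embedding (ties by
    row index), then keep as edges the ``n_edges`` highest-Tanimoto pairs
    among all members (query included).  Members without a SMILES stay as
    nodes but contribute no pairs."""
    coords2d = np.asarray(coords2d, dtype=float)
    n = coords2d.shape[0]
    if not 0 < k < n:
        raise ValueError("k must satisfy 0 < k < N")
    dist = np.linalg.norm(coords2d - coords2d[query_idx], axis=1)
    others = np.array([i for i in range(n) if i != query_idx])
    order = others[np.lexsort((others, dist[others]))][:k]
    members = [int(query_idx)] + [int(i) for i in order]

    fps: dict[int, Fingerprint] = {}
    for i in members:
        smi = smiles_per_row[i]
        if smi:
            try:
                fps[i] = fingerprint_from_smiles(smi, width=width, depth=depth)
            except ValueError:
                logger.warning("row %d: invalid SMILES excluded from pairs", i)
        else:
            logger.warning("row %d: missing SMILES; node kept, pairs excluded", i)

    pairs = []
    for ai in range(len(members)):
        for bi in range(ai + 1, len(members)):
            a, b = members[ai], members[bi]
            if a in fps and b in fps:
                pairs.append((tanimoto(fps[a], fps[b]), a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    g = nx.Graph()
    g.add_nodes_from(members)
    for tc, a, b in pairs[:n_edges]:
        g.add_edge(a, b, tc=tc)
    return g


# ---------------------------------------------------------------------------
# nearest-neighbor target identification
# ---------------------------------------------------------------------------

def identify_target(new_logits: np.ndarray, reference, k: int = 100,
                    selected_idx: np.ndarray | None = None) -> str:
    """Majority target label among the ``k`` nearest reference rows by
    Euclidean distance in logit space (optionally restricted to the selected
    high-variance columns).  Label ties break by summed inverse distance,
    then lexicographically."""
    from .embedding import LogitMatrix

    if not isinstance(reference, LogitMatrix):
        raise TypeError("reference must be a LogitMatrix")
    new_logits = np.asarray(new_logits, dtype=float).ravel()
    X = reference.values
    if new_logits.size != X.shape[1]:
        raise ValueError("vector length does not match reference matrix width")
    if selected_idx is not None:
        X = X[:, selected_idx]
        new_logits = new_logits[selected_idx]
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of reference rows")
    dist = np.linalg.norm(X - new_logits, axis=1)
    idx = np.lexsort((np.arange(dist.size), dist))[:k]
    labels = reference.row_meta["target"].to_numpy()[idx]
    counts: dict[str, int] = {}
    inv: dict[str, float] = {}
    for i, lab in zip(idx, labels):
        counts[lab] = counts.get(lab, 0) + 1
        inv[lab] = inv.get(lab, 0.0) + 1.0 / (dist[i] + 1e-12)
    return min(counts, key=lambda lab: (-counts[lab], -inv[lab], lab))


def load_score_table(path) -> "pd.DataFrame":
    """Adapter for externally produced benchmark score tables:
    TSV with columns (query, candidate, score)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    expected = {"query", "candidate", "score"}
    if not expected.issubset(df.columns):
        raise ValueError(f"score table must have columns {sorted(expected)}")
    return df
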