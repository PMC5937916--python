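"""Corpus statistics: frequency, adjacency, associative strength, semantic
diversity, and validation against the environment's design targets.

Associative strength between words x and y is the symmetric adjacency
statistic A = (N_xy/N_x + N_yx/N_y) / 2, where N_xy counts occasions on
which x was immediately followed by y *within* an episode.  Semantic
diversity (SemD) of a word is -log of the mean pairwise cosine similarity
among the latent-space vectors of all episodes containing it, with episode
vectors obtained by truncated SVD of the episode-by-word count matrix (the
LSA recipe applied to the artificial corpus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats as sps
from sklearn.decomposition import TruncatedSVD

from .corpus import Corpus
from .vocabulary import ABSTRACT, CONCRETE, Concept

__all__ = ["CorpusStats", "LSAConfig", "compute_stats", "associative_strength",
           "cooccurrence_rate", "semantic_diversity", "validate_corpus"]

_SIM_FLOOR = 1e-6


class UndefinedStatisticError(ValueError):
    """Raised for statistics of zero-frequency (or single-context) words."""


@dataclass(frozen=True)
class LSAConfig:
    # 18 latent dimensions: on a 35-topic corpus this compresses episodes from
    # related topics onto shared components, giving within-cluster context
    # similarities (hence the SemD scale) that match the environment's design
    # targets.  See docs/methods.md.
    n_dims: int = 18
    seed: int = 0  # randomized-SVD seed; results are essentially deterministic


@dataclass
class CorpusStats:
    freq: np.ndarray  # (64,) occurrence counts N_x
    next_counts: np.ndarray  # (64, 64) adjacency counts N_xy
    semd: np.ndarray | None = None  # (64,) semantic diversity, NaN if undefined
    n_episodes: int = 0

    @property
    def assoc(self) -> np.ndarray:
        """Full symmetric associative-strength matrix (NaN where undefined)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            fwd = self.next_counts / self.freq[:, None]
            a = 0.5 * (fwd + fwd.T)
        return a


def compute_stats(corpus: Corpus, lsa: LSAConfig | None = None,
                  n_words: int = 64, with_semd: bool = True) -> CorpusStats:
    concepts = corpus.concepts
    freq = np.bincount(concepts.ravel(), minlength=n_words).astype(np.int64)
    x = concepts[:, :-1].ravel().astype(np.int64)
    y = concepts[:, 1:].ravel().astype(np.int64)
    next_counts = np.zeros((n_words, n_words), dtype=np.int64)
    np.add.at(next_counts, (x, y), 1)
    stats = CorpusStats(freq=freq, next_counts=next_counts,
                        n_episodes=len(corpus))
    if with_semd:
        stats.semd = semantic_diversity(corpus, lsa or LSAConfig(),
                                        n_words=n_words)
    return stats


def associative_strength(stats: CorpusStats, x: int, y: int) -> float:
    """A = (N_xy/N_x + N_yx/N_y) / 2; error if either word never occurs."""
    if stats.freq[x] == 0 or stats.freq[y] == 0:
        raise UndefinedStatisticError(f"zero-frequency word in pair ({x}, {y})")
    return 0.5 * (stats.next_counts[x, y] / stats.freq[x]
                  + stats.next_counts[y, x] / stats.freq[y])


def cooccurrence_rate(stats: CorpusStats, probe: int, target: int) -> float:
    """Proportion of probe occurrences immediately followed by the target."""
    if stats.freq[probe] == 0:
        raise UndefinedStatisticError(f"zero-frequency probe {probe}")
    return stats.next_counts[probe, target] / stats.freq[probe]


def semantic_diversity(corpus: Corpus, lsa: LSAConfig | None = None,
                       n_words: int = 64) -> np.ndarray:
    """Per-word SemD over the corpus; NaN for words in < 2 episodes.

    Episode count vectors are reduced to ``lsa.n_dims`` dimensions by
    truncated SVD; the mean pairwise cosine among a word's episode vectors is
    computed in closed form from the sum of the unit vectors, floored at 1e-6
    before the log.
    """
    lsa = lsa or LSAConfig()
    n = len(corpus)
    rows = np.repeat(np.arange(n), corpus.concepts.shape[1])
    cols = corpus.concepts.ravel().astype(np.int64)
    counts = sp.coo_matrix((np.ones(rows.size), (rows, cols)),
                           shape=(n, n_words)).tocsr()
    counts.sum_duplicates()
    k = min(lsa.n_dims, n_words - 1, n - 1)
    vecs = TruncatedSVD(n_components=k, random_state=lsa.seed).fit_transform(counts)
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms == 0] = 1.0
    unit = vecs / norms[:, None]

    presence = (counts > 0).tocsc()
    semd = np.full(n_words, np.nan)
    for w in range(n_words):
        idx = presence.indices[presence.indptr[w]:presence.indptr[w + 1]]
        m = idx.size
        if m < 2:
            continue
        s = unit[idx].sum(axis=0)
        mean_cos = (s @ s - m) / (m * (m - 1))
        semd[w] = -np.log(max(mean_cos, _SIM_FLOOR))
    return semd


def validate_corpus(corpus: Corpus, stats: CorpusStats, vocab: list[Concept],
                    homonym_trials: dict[int, tuple[int, int]],
                    bands: dict[str, tuple[float, float]] | None = None) -> dict:
    """Report-only check of the corpus against its design targets.

    ``homonym_trials`` maps homonym id -> (dominant target id, subordinate
    target id).  Returns a dict with the measured quantities and, when
    ``bands`` supplies (lo, hi) intervals, per-check pass flags.
    """
    concrete = np.array([c.cls == CONCRETE for c in vocab])
    abstract = np.array([c.cls == ABSTRACT for c in vocab])
    freq, semd = stats.freq, stats.semd
    logf = np.log(np.maximum(freq, 1))
    imageability = concrete.astype(float)

    report: dict[str, float | bool] = {
        "freq_ratio": float(freq.max() / max(freq.min(), 1)),
        "semd_concrete_mean": float(np.nanmean(semd[concrete])),
        "semd_abstract_mean": float(np.nanmean(semd[abstract])),
        "semd_min": float(np.nanmin(semd)),
        "semd_max": float(np.nanmax(semd)),
    }
    ok = ~np.isnan(semd)
    report["r_freq_semd"] = float(sps.pearsonr(logf[ok], semd[ok])[0])
    # partial r(frequency, imageability | SemD)
    def _resid(a, b):
        beta = np.polyfit(b, a, 1)
        return a - np.polyval(beta, b)
    report["partial_r_freq_imageability"] = float(
        sps.pearsonr(_resid(logf[ok], semd[ok]), _resid(imageability[ok], semd[ok]))[0]
    )
    dom = [cooccurrence_rate(stats, h, t_dom)
           for h, (t_dom, _) in homonym_trials.items()]
    sub = [cooccurrence_rate(stats, h, t_sub)
           for h, (_, t_sub) in homonym_trials.items()]
    report["coocc_dominant_mean"] = float(np.mean(dom))
    report["coocc_subordinate_mean"] = float(np.mean(sub))

    if bands:
        for key, (lo, hi) in bands.items():
            report[f"{key}_ok"] = bool(lo <= report[key] <= hi)
    return report
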