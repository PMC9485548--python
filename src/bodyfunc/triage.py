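"""Page triage: structural line features, PCA projection, body-function
term ranking, and stratified sampling.

Before annotation or extraction, a large OCR'd corpus needs triage: pages
with garbled OCR cluster away from clean ones when per-line structural
features (case, indentation, punctuation/digit density, lexical-cohesion
shifts between consecutive lines) are aggregated per page and projected
onto their first two principal components, and pages worth annotating are
found by ranking on body-function term frequency and drawing a stratified
sample across the ranked list.

The feature set here is a compact named subset (means and standard
deviations over lines of ~9 per-line measurements plus page-level counts)
rather than an exhaustive one; add dimensions via ``line_structure_features``.
"""

from __future__ import annotations

import random
import string

import numpy as np

from .decompose import Line, PageDoc, tokenize
from .lexicon import Lexicon, lookup

LINE_FEATURES = [
    "starts_upper",
    "first_token_case",
    "leading_whitespace_count",
    "indented_vs_prev",
    "punct_char_count",
    "digit_char_count",
    "line_length",
    "token_count",
    "cohesion_shift",
]


def _token_case(token: str) -> int:
    """0=lower, 1=Upper, 2=ALLCAPS, 3=other."""
    if not token:
        return 3
    if token.islower():
        return 0
    if len(token) > 1 and token.isupper():
        return 2
    if token[:1].isupper() and token[1:].islower():
        return 1
    if token[:1].isupper() and len(token) == 1:
        return 2
    return 3


def line_structure_features(line: Line, prev_line: Line | None = None) -> dict[str, float]:
    """Structural measurements for one line (empty line -> all zeros).

    ``cohesion_shift`` is 1 minus the shared-token Jaccard similarity with
    the previous line, a text-tiling-style topic-shift signal.
    """
    content = line.text.rstrip("\n")
    if not content.strip():
        return {name: 0.0 for name in LINE_FEATURES}
    stripped = content.lstrip()
    leading_ws = len(content) - len(stripped)
    tokens = [t.text for t in tokenize(content)]
    first = tokens[0] if tokens else ""
    prev_content = prev_line.text.rstrip("\n") if prev_line is not None else ""
    prev_leading = len(prev_content) - len(prev_content.lstrip())
    prev_tokens = {t.text.lower() for t in tokenize(prev_content)}
    cur_tokens = {t.lower() for t in tokens}
    union = cur_tokens | prev_tokens
    jaccard = len(cur_tokens & prev_tokens) / len(union) if union else 0.0
    return {
        "starts_upper": float(stripped[:1].isupper()),
        "first_token_case": float(_token_case(first)),
        "leading_whitespace_count": float(leading_ws),
        "indented_vs_prev": float(prev_line is not None and leading_ws > prev_leading),
        "punct_char_count": float(sum(c in string.punctuation for c in content)),
        "digit_char_count": float(sum(c.isdigit() for c in content)),
        "line_length": float(len(content)),
        "token_count": float(len(tokens)),
        "cohesion_shift": 1.0 - jaccard,
    }


PAGE_FEATURES = (
    [f"{name}_mean" for name in LINE_FEATURES]
    + [f"{name}_sd" for name in LINE_FEATURES]
    + ["n_lines", "n_chars", "n_tokens"]
)


def page_features(page: PageDoc) -> np.ndarray:
    """Aggregate per-line features as mean and standard deviation, plus
    page-level counts; an empty page maps to the zero vector."""
    rows = []
    prev = None
    for line in page.lines:
        feats = line_structure_features(line, prev)
        rows.append([feats[name] for name in LINE_FEATURES])
        prev = line
    if not rows:
        return np.zeros(len(PAGE_FEATURES))
    matrix = np.asarray(rows, dtype=float)
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0)
    counts = [float(len(page.lines)), float(len(page.text)), float(len(page.tokens))]
    return np.concatenate([means, sds, counts])


def pca_project(matrix: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized PCA via singular value decomposition.

    Columns are centered and scaled to unit variance (zero-variance
    columns dropped); components carry a fixed sign convention (the
    largest-magnitude loading of each component is positive) so results
    are reproducible across libraries.  Returns (scores n x k, loadings
    d x k, explained variance ratio).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    if k > Z.shape[1]:
        raise ValueError(f"k={k} exceeds usable rank {Z.shape[1]}")
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    components = vt[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    scores = Z @ components.T
    var = svals**2 / Z.shape[0]
    explained = var[:k] / var.sum()
    loadings = np.zeros((X.shape[1], k))
    loadings[keep] = components.T
    return scores, loadings, explained


def bf_term_rank(
    pages: list[PageDoc], bf_terms: Lexicon
) -> list[tuple[str, int]]:
    """Rank pages by the number of body-function term hits (descending),
    ties broken by page id (stable)."""
    counts = []
    for page in pages:
        hits = lookup(page.tokens, bf_terms)
        counts.append((page.page_id, len(hits)))
    counts.sort(key=lambda item: (-item[1], item[0]))
    return counts


def stratified_sample(
    ranked: list[tuple[str, int]], n_strata: int, n_total: int, seed: int
) -> list[str]:
    """Draw ``n_total`` page ids from ``n_strata`` equal-count bins of the
    ranked list, uniformly without replacement per bin; remainder quota
    goes to the densest (top-ranked) bins.  Deterministic for a seed."""
    if n_total > len(ranked):
        raise ValueError("n_total exceeds corpus size")
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    rng = random.Random(seed)
    ids = [page_id for page_id, _ in ranked]
    strata: list[list[str]] = []
    base, rem = divmod(len(ids), n_strata)
    cursor = 0
    for i in range(n_strata):
        size = base + (1 if i < rem else 0)
        strata.append(ids[cursor : cursor + size])
        cursor += size
    if any(not s for s in strata):
        raise ValueError("empty stratum (n_strata too large for corpus)")
    quota, extra = divmod(n_total, n_strata)
    sample: list[str] = []
    for i, stratum in enumerate(strata):
        want = quota + (1 if i < extra else 0)
        want = min(want, len(stratum))
        sample.extend(rng.sample(stratum, want))
    # redistribute shortfall from exhausted strata
    short = n_total - len(sample)
    if short:
        leftover = [pid for s in strata for pid in s if pid not in set(sample)]
        sample.extend(rng.sample(leftover, short))
    return sample
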