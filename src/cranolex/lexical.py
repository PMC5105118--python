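"""ASJP-style linguistic distances from weighted word alignment.

A doculect is a documented language variety carrying words for 40 core
concepts in the 41-symbol ASJPcode transcription. Word-pair similarity is
the global (Needleman-Wunsch) alignment score under a sound-pair log-odds
weight matrix: each aligned sound pair contributes the log-odds of the
sounds being historically related versus matched by chance, and gap runs
pay affine penalties. Doculect similarity then calibrates the synonymous
scores against the empirical distribution of non-synonymous (cross-concept)
scores: per shared concept, the fraction of the non-synonymous pool
strictly below the best synonymous score; the doculect distance is one
minus the mean of these fractions, so it lives in [0, 1].

Population-level distances (L) average doculect distances over candidate
doculects selected by ethnonym, island, or 500-km-radius heuristics;
family-level distances (F) average over cross-family doculect pairs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from cranolex.errors import (
    FormatError,
    InvalidParameterError,
    NoCandidatesError,
    UndefinedDistanceError,
)
from cranolex.geography import GeoPoint, great_circle

#: The 41-symbol ASJPcode alphabet: 7 vowels and 34 consonants.
ASJP_VOWELS = "ieE3auo"
ASJP_CONSONANTS = "pbfvmw8tdszcnrlSZCjT5ykgxNqGX7hL4!"
ASJP_ALPHABET = ASJP_VOWELS + ASJP_CONSONANTS

#: The 40 core concepts of an ASJP word list, in canonical order.
CONCEPTS = (
    "I", "you", "we", "one", "two", "person", "fish", "dog", "louse", "tree",
    "leaf", "skin", "blood", "bone", "horn", "ear", "eye", "nose", "tooth",
    "tongue", "knee", "hand", "breast", "liver", "drink", "see", "hear",
    "die", "come", "sun", "star", "water", "stone", "fire", "path",
    "mountain", "night", "full", "new", "name",
)

GAP = "-"
MISSING_ENTRY = "XXX"
LOAN_MARKER = "%"
NONSYN_POOL_CAP = 20000
NONSYN_POOL_SEED = 77003  # fixed: pool subsampling must not depend on caller state


@dataclass
class Doculect:
    """A word list for one documented language variety."""

    name: str
    classification: str = ""  # "FAMILY.GENUS" WALS-style label
    lat: float | None = None
    lon: float | None = None
    island: str | None = None
    words: dict = field(default_factory=dict)  # concept -> list of ASJPcode strings

    @property
    def family(self) -> str:
        return self.classification.split(".", 1)[0] if self.classification else ""

    def concepts(self) -> set:
        return {c for c, ws in self.words.items() if ws}


@dataclass
class WeightMatrix:
    """Symmetric sound-pair log-odds weights plus affine gap penalties."""

    sound_pair_weights: dict  # (symbol, symbol) -> weight, stored both orders
    gap_open: float = -2.5
    gap_extend: float = -2.5

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise InvalidParameterError("gap penalties must be <= 0")
        sym = {}
        for (a, b), v in self.sound_pair_weights.items():
            v = float(v)
            if (b, a) in self.sound_pair_weights and not math.isclose(
                float(self.sound_pair_weights[(b, a)]), v, abs_tol=1e-9
            ):
                raise InvalidParameterError(f"asymmetric weight for pair ({a}, {b})")
            sym[(a, b)] = v
            sym[(b, a)] = v
        self.sound_pair_weights = sym

    def weight(self, a: str, b: str) -> float:
        try:
            return self.sound_pair_weights[(a, b)]
        except KeyError:
            raise InvalidParameterError(f"no weight defined for sound pair ({a}, {b})")

    @property
    def alphabet(self) -> set:
        return {a for a, _ in self.sound_pair_weights}


def uniform_weights(
    alphabet: str = ASJP_ALPHABET,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap: float = -2.5,
) -> WeightMatrix:
    """Identity-favoring weight scheme (also the estimation start point)."""
    weights = {}
    for a in alphabet:
        for b in alphabet:
            weights[(a, b)] = match if a == b else mismatch
    return WeightMatrix(weights, gap_open=gap, gap_extend=gap)


@dataclass
class AlignmentResult:
    aligned_pairs: list  # list of (symbol-or-gap, symbol-or-gap)
    score: float

    @property
    def aligned_a(self) -> str:
        return "".join(a for a, _ in self.aligned_pairs)

    @property
    def aligned_b(self) -> str:
        return "".join(b for _, b in self.aligned_pairs)


NEG_INF = float("-inf")


def align_words(a: str, b: str, w: WeightMatrix) -> AlignmentResult:
    """Global alignment of two ASJPcode strings maximizing the weighted score.

    Affine gap runs cost ``gap_open + (len - 1) * gap_extend`` (the default
    matrices use equal penalties, i.e. a linear gap model). Ties are broken
    deterministically: substitution preferred over a gap, then a gap in the
    second string (upper cell) over a gap in the first.
    """
    if not a or not b:
        raise InvalidParameterError("cannot align empty strings")
    n, m = len(a), len(b)
    go, ge = w.gap_open, w.gap_extend
    wt = w.weight  # validates symbols on first use

    # Gotoh three-state DP: M substitution, X gap in b (consumes a), Y gap in a
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0][j] = go + (j - 1) * ge
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = wt(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + go, X[i - 1][j] + ge, Y[i - 1][j] + go)
            Y[i][j] = max(M[i][j - 1] + go, Y[i][j - 1] + ge, X[i][j - 1] + go)

    # traceback with deterministic tie-breaking: M (substitution), then X
    # (gap in b, i.e. the upper cell), then Y
    def _pick(candidates):
        # candidates: list of (state, value) in preference order
        best_val = max(v for _, v in candidates)
        for st, v in candidates:
            if v >= best_val - 1e-12:
                return st
        return candidates[0][0]

    pairs = []
    i, j = n, m
    state = _pick([("M", M[n][m]), ("X", X[n][m]), ("Y", Y[n][m])])
    score = {"M": M, "X": X, "Y": Y}[state][n][m]
    while i > 0 or j > 0:
        if state == "M":
            pairs.append((a[i - 1], b[j - 1]))
            state = _pick(
                [
                    ("M", M[i - 1][j - 1]),
                    ("X", X[i - 1][j - 1]),
                    ("Y", Y[i - 1][j - 1]),
                ]
            )
            i, j = i - 1, j - 1
        elif state == "X":
            pairs.append((a[i - 1], GAP))
            state = _pick(
                [
                    ("M", M[i - 1][j] + go),
                    ("X", X[i - 1][j] + ge),
                    ("Y", Y[i - 1][j] + go),
                ]
            )
            i -= 1
        else:
            pairs.append((GAP, b[j - 1]))
            state = _pick(
                [
                    ("M", M[i][j - 1] + go),
                    ("Y", Y[i][j - 1] + ge),
                    ("X", X[i][j - 1] + go),
                ]
            )
            j -= 1
    pairs.reverse()
    return AlignmentResult(aligned_pairs=pairs, score=score)


def align_score(a: str, b: str, w: WeightMatrix) -> float:
    """Alignment score only (skips traceback; used in the inner loops)."""
    if not a or not b:
        raise InvalidParameterError("cannot align empty strings")
    n, m = len(a), len(b)
    go, ge = w.gap_open, w.gap_extend
    wt = w.sound_pair_weights
    prev_m = [NEG_INF] * (m + 1)
    prev_x = [NEG_INF] * (m + 1)
    prev_y = [NEG_INF] * (m + 1)
    prev_m[0] = 0.0
    for j in range(1, m + 1):
        prev_y[j] = go + (j - 1) * ge
    for i in range(1, n + 1):
        cur_m = [NEG_INF] * (m + 1)
        cur_x = [NEG_INF] * (m + 1)
        cur_y = [NEG_INF] * (m + 1)
        cur_x[0] = go + (i - 1) * ge
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = wt[(ai, b[j - 1])]
            cur_m[j] = max(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1]) + s
            cur_x[j] = max(prev_m[j] + go, prev_x[j] + ge, prev_y[j] + go)
            cur_y[j] = max(cur_m[j - 1] + go, cur_y[j - 1] + ge, cur_x[j - 1] + go)
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y
    return max(prev_m[m], prev_x[m], prev_y[m])


def doculect_similarity(d1: Doculect, d2: Doculect, w: WeightMatrix) -> tuple[float, float]:
    """Calibrated similarity and distance between two doculects, both in [0, 1].

    For each shared concept the best synonymous alignment score is placed
    within the empirical distribution of non-synonymous (cross-concept)
    scores; similarity is the mean of those strict-CDF values and distance
    is its complement. The non-synonymous pool is capped at 20,000 pairs by
    fixed-seed subsampling, so results are deterministic.
    """
    shared = sorted(d1.concepts() & d2.concepts())
    if not shared:
        raise UndefinedDistanceError(f"{d1.name} and {d2.name} share no concepts")

    syn_scores = {}
    for c in shared:
        syn_scores[c] = max(
            align_score(x, y, w) for x in d1.words[c] for y in d2.words[c]
        )

    concepts1 = sorted(d1.concepts())
    concepts2 = sorted(d2.concepts())
    cross = [
        (x, y)
        for c1 in concepts1
        for c2 in concepts2
        if c1 != c2
        for x in d1.words[c1]
        for y in d2.words[c2]
    ]
    if not cross:
        raise UndefinedDistanceError(
            f"{d1.name} and {d2.name}: no non-synonymous pairs to calibrate against"
        )
    if len(cross) > NONSYN_POOL_CAP:
        rng = np.random.default_rng(NONSYN_POOL_SEED)
        idx = rng.choice(len(cross), size=NONSYN_POOL_CAP, replace=False)
        cross = [cross[i] for i in idx]
    pool = np.sort(np.array([align_score(x, y, w) for x, y in cross]))

    n_pool = len(pool)
    sims = [
        np.searchsorted(pool, syn_scores[c], side="left") / n_pool for c in shared
    ]
    similarity = float(np.mean(sims))
    return similarity, 1.0 - similarity


def doculect_distance(d1: Doculect, d2: Doculect, w: WeightMatrix) -> float:
    return doculect_similarity(d1, d2, w)[1]


# ---------------------------------------------------------------------------
# candidate selection and aggregation


@dataclass
class PopulationMeta:
    """Selection metadata for matching a sampled population to doculects."""

    name: str
    ethnonyms: tuple = ()  # explicit doculect names or classification labels
    islands: tuple = ()
    lat: float | None = None
    lon: float | None = None
    continent: str = ""


def select_candidates(
    population: PopulationMeta,
    doculects: list[Doculect],
    radius_km: float = 500.0,
) -> list[Doculect]:
    """Candidate doculects for a population by three ordered heuristics.

    (1) an explicit ethnonym restricts to name/classification matches;
    (2) otherwise an island label restricts to doculects on those islands;
    (3) otherwise every doculect within ``radius_km`` great-circle km of
    the population's coordinates is a candidate.
    """
    if population.ethnonyms:
        wanted = {e.lower() for e in population.ethnonyms}
        out = [
            d
            for d in doculects
            if d.name.lower() in wanted
            or d.family.lower() in wanted
            or d.classification.lower() in wanted
        ]
    elif population.islands:
        wanted = {i.lower() for i in population.islands}
        out = [d for d in doculects if d.island and d.island.lower() in wanted]
    else:
        if population.lat is None or population.lon is None:
            raise InvalidParameterError(
                f"population {population.name}: no ethnonym, island, or coordinates"
            )
        anchor = GeoPoint(population.lat, population.lon)
        out = [
            d
            for d in doculects
            if d.lat is not None
            and d.lon is not None
            and great_circle(anchor, GeoPoint(d.lat, d.lon)) <= radius_km
        ]
    if not out:
        raise NoCandidatesError(f"no candidate doculect for population {population.name}")
    return out


def population_distance(
    candidates_a: list[Doculect], candidates_b: list[Doculect], w: WeightMatrix
) -> float:
    """L entry: mean doculect distance over all cross pairs of candidates."""
    if not candidates_a or not candidates_b:
        raise InvalidParameterError("candidate sets must be non-empty")
    values = [
        doculect_distance(da, db, w) for da in candidates_a for db in candidates_b
    ]
    return float(np.mean(values))


def family_distance(
    family_a: list[Doculect], family_b: list[Doculect], w: WeightMatrix
) -> float:
    """F entry: mean doculect distance over all cross-family pairs."""
    if not family_a or not family_b:
        raise InvalidParameterError("families must be non-empty")
    names_a = {d.name for d in family_a}
    if names_a & {d.name for d in family_b}:
        raise InvalidParameterError("families must be disjoint")
    values = [doculect_distance(da, db, w) for da in family_a for db in family_b]
    return float(np.mean(values))


def population_distance_matrix(candidates: dict, w: WeightMatrix):
    """Symmetric L matrix over a {population: [Doculect, ...]} mapping."""
    import pandas as pd

    labels = list(candidates)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = population_distance(candidates[labels[i]], candidates[labels[j]], w)
            values[i, j] = values[j, i] = d
    return pd.DataFrame(values, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# weight estimation


def estimate_weights(
    cognate_training_pairs: list[tuple[str, str]],
    background_pairs: list[tuple[str, str]],
    alphabet: str = ASJP_ALPHABET,
    n_iter: int = 3,
    gap: float = -2.5,
    pseudo_count: float = 0.5,
) -> WeightMatrix:
    """Iteratively estimate sound-pair log-odds weights from word pairs.

    Starting from an identity-favoring scheme, each round aligns the
    plausibly related (cognate) pairs and the background pairs with the
    current weights, tallies aligned symbol pairs on each side, and sets
    weight(x, y) = log2 of the ratio of relative frequencies, with additive
    smoothing (pseudo-count 0.5) so unseen pairs stay finite. Gap penalties
    are not re-estimated. Deterministic for a fixed training set.
    """
    if not cognate_training_pairs or not background_pairs:
        raise InvalidParameterError("need non-empty related and background samples")
    w = uniform_weights(alphabet, gap=gap)
    symbols = list(alphabet)
    for _ in range(n_iter):
        rel = _pair_counts(cognate_training_pairs, w, symbols, pseudo_count)
        bg = _pair_counts(background_pairs, w, symbols, pseudo_count)
        weights = {}
        for i, x in enumerate(symbols):
            for y in symbols[i:]:
                v = math.log2(rel[(x, y)] / bg[(x, y)])
                weights[(x, y)] = v
                weights[(y, x)] = v
        w = WeightMatrix(weights, gap_open=gap, gap_extend=gap)
    return w


def _pair_counts(pairs, w, symbols, pseudo_count):
    counts = {}
    for i, x in enumerate(symbols):
        for y in symbols[i:]:
            counts[(x, y)] = pseudo_count
            counts[(y, x)] = pseudo_count
    total = pseudo_count * len(symbols) * (len(symbols) + 1) / 2
    for a, b in pairs:
        res = align_words(a, b, w)
        for x, y in res.aligned_pairs:
            if x == GAP or y == GAP:
                continue
            key = (x, y) if (x, y) in counts else (y, x)
            counts[key] += 1.0
            if x != y:
                counts[(y, x)] = counts[key]
            total += 1.0
    # normalize to relative frequencies over unordered pairs
    return {k: v / total for k, v in counts.items()}


# ---------------------------------------------------------------------------
# ASJP wordlist file dialect


_NAME_RE = re.compile(r"^(?P<name>[^{\s][^{]*)\{(?P<cls>[^}]*)\}\s*$")


def parse_asjp(path) -> list[Doculect]:
    """Parse an ASJP-style wordlist file into doculects.

    Dialect (documented in the README): a name line ``NAME{FAMILY.GENUS}``,
    a metadata line with latitude and longitude (optionally
    ``island=LABEL``), then numbered concept lines
    ``<index> <gloss>\\t<word>[, <word> ...]``. ``XXX`` marks a missing
    entry; a ``%`` prefix marks a loanword (retained, marker stripped).
    """
    doculects = []
    current: Doculect | None = None
    expect_meta = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            m = _NAME_RE.match(line)
            if m and not line[0].isdigit():
                current = Doculect(name=m.group("name").strip(), classification=m.group("cls"))
                doculects.append(current)
                expect_meta = True
                continue
            if current is None:
                raise FormatError(f"{path}:{lineno}: content before any doculect header")
            if expect_meta:
                expect_meta = False
                parts = line.split()
                try:
                    current.lat = float(parts[0])
                    current.lon = float(parts[1])
                except (IndexError, ValueError):
                    raise FormatError(f"{path}:{lineno}: metadata line needs lat lon")
                for extra in parts[2:]:
                    if extra.startswith("island="):
                        current.island = extra.split("=", 1)[1]
                continue
            parts = line.split("\t")
            head = parts[0].split()
            try:
                idx = int(head[0])
            except (IndexError, ValueError):
                raise FormatError(f"{path}:{lineno}: malformed concept index")
            if not (1 <= idx <= len(CONCEPTS)):
                raise FormatError(f"{path}:{lineno}: concept index {idx} out of range")
            concept = CONCEPTS[idx - 1]
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: missing word field")
            words = []
            for token in parts[1].split(","):
                token = token.strip()
                if not token or token == MISSING_ENTRY:
                    continue
                if token.startswith(LOAN_MARKER):
                    token = token[len(LOAN_MARKER):]
                for ch in token:
                    if ch not in ASJP_ALPHABET:
                        raise FormatError(
                            f"{path}:{lineno}: symbol {ch!r} outside ASJPcode"
                        )
                words.append(token)
            if words:
                current.words[concept] = words
    return doculects


def write_asjp(doculects: list[Doculect], path) -> None:
    """Write doculects in the dialect :func:`parse_asjp` reads (round-trip safe)."""
    with open(path, "w") as fh:
        for d in doculects:
            fh.write(f"{d.name}{{{d.classification}}}\n")
            meta = f"  {d.lat if d.lat is not None else 0.0:.4f} {d.lon if d.lon is not None else 0.0:.4f}"
            if d.island:
                meta += f" island={d.island}"
            fh.write(meta + "\n")
            for idx, concept in enumerate(CONCEPTS, 1):
                if concept in d.words and d.words[concept]:
                    fh.write(f"{idx} {concept}\t{', '.join(d.words[concept])}\n")


def read_weight_matrix(path) -> WeightMatrix:
    """Read a weight TSV: '# gap_open', '# gap_extend' headers, then symbol pairs."""
    weights = {}
    gap_open = gap_extend = -2.5
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("gap_open"):
                    gap_open = float(body.split()[-1])
                elif body.startswith("gap_extend"):
                    gap_extend = float(body.split()[-1])
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'symbol<TAB>symbol<TAB>weight'")
            a, b, v = parts
            weights[(a, b)] = float(v)
    return WeightMatrix(weights, gap_open=gap_open, gap_extend=gap_extend)


def write_weight_matrix(w: WeightMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gap_open {w.gap_open}\n")
        fh.write(f"# gap_extend {w.gap_extend}\n")
        seen = set()
        for (a, b), v in sorted(w.sound_pair_weights.items()):
            if (b, a) in seen:
                continue
            seen.add((a, b))
            fh.write(f"{a}\t{b}\t{v:.10g}\n")
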