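"""Synthetic worlds with known divergence structure for parameter recovery.

A world is a rooted ultrametric population tree. From it the module
generates (i) per-specimen 3D landmark configurations whose population
mean shapes diverge by Brownian motion on the raw coordinates, with
isotropic Gaussian within-population noise; (ii) 40-concept ASJPcode word
lists evolving by cognate replacement and per-segment sound substitution;
and (iii) population coordinates along a great-circle corridor ordered by
tree traversal, so geographic distance tracks divergence. Every generator
is a pure function of (params, seed); sub-generators draw from streams
split off the world seed by fixed offsets so stages can be re-run
independently and still agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from cranolex.errors import InvalidParameterError
from cranolex.geography import GeoPoint, great_circle
from cranolex.lexical import ASJP_ALPHABET, CONCEPTS, Doculect
from cranolex.morphometrics import LandmarkConfiguration, LandmarkPartition

# fixed sub-stream offsets off the world seed
_OFFSET_TREE = 0
_OFFSET_LANDMARKS = 1
_OFFSET_WORDS = 2
_OFFSET_GEO = 3
_SEED_MOD = 2**31


def _substream(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng((int(seed) + offset) % _SEED_MOD)


@dataclass
class SyntheticParams:
    """Generation parameters; defaults give a moderately diverged world.

    ``brownian_rate`` is the per-coordinate variance accrued per unit
    branch length (mm^2 per time unit on the raw landmark scale);
    ``noise_sd`` the within-population landmark standard deviation (mm);
    the lexical rates are per-concept and per-segment hazards per unit
    time. Tree branch lengths are in coalescent units with expected
    pairwise divergence 2.
    """

    n_pops: int = 8
    n_specimens_per_pop: int = 20
    n_landmarks: int = 32
    brownian_rate: float = 4.0
    noise_sd: float = 1.0
    cognate_replacement_rate: float = 0.3
    sound_substitution_rate: float = 0.2
    sphere_radius_km: float = 6373.0

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise InvalidParameterError("n_pops must be >= 2")
        if self.n_landmarks < 4:
            raise InvalidParameterError("n_landmarks must be >= 4")
        for name in (
            "brownian_rate",
            "noise_sd",
            "cognate_replacement_rate",
            "sound_substitution_rate",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.n_specimens_per_pop < 2:
            raise InvalidParameterError("n_specimens_per_pop must be >= 2")


@dataclass
class TreeNode:
    """A node of a rooted ultrametric tree (height = distance to its tips)."""

    name: str
    height: float = 0.0
    children: list = field(default_factory=list)
    branch_length: float = 0.0  # to parent

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        def fmt(node):
            if node.is_leaf:
                return f"{node.name}:{node.branch_length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.branch_length:.10g}"

        return fmt(self).rsplit(":", 1)[0] + ";"


@dataclass
class SyntheticWorld:
    tree: TreeNode
    populations: list
    divergence: pd.DataFrame  # pairwise tree distance (2 x MRCA height)
    seed: int

    def leaf_order(self) -> list:
        return [l.name for l in self.tree.leaves()]


def _divergence_from_tree(root: TreeNode, populations: list) -> pd.DataFrame:
    idx = {name: i for i, name in enumerate(populations)}
    n = len(populations)
    d = np.zeros((n, n))

    def visit(node):
        if node.is_leaf:
            return [node.name]
        groups = [visit(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2.0 * node.height
        return [name for g in groups for name in g]

    visit(root)
    return pd.DataFrame(d, index=populations, columns=populations)


def simulate_tree(params: SyntheticParams, seed: int, kind: str = "coalescent") -> SyntheticWorld:
    """Random ultrametric population tree over ``n_pops`` tips.

    ``coalescent``: Kingman coalescent with pairwise coalescence rate 1,
    so any pair of tips has expected divergence (twice the coalescence
    time) equal to 2 regardless of n. ``balanced``: a fully balanced
    binary tree of unit height (n_pops must be a power of two).
    """
    rng = _substream(seed, _OFFSET_TREE)
    n = params.n_pops
    populations = [f"pop{i:02d}" for i in range(n)]
    if kind == "coalescent":
        lineages = [TreeNode(name=p, height=0.0) for p in populations]
        t = 0.0
        while len(lineages) > 1:
            k = len(lineages)
            t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
            i, j = sorted(rng.choice(k, size=2, replace=False))
            a = lineages.pop(j)
            b = lineages.pop(i)
            parent = TreeNode(name="", height=t, children=[b, a])
            for c in parent.children:
                c.branch_length = t - c.height
            lineages.append(parent)
        root = lineages[0]
    elif kind == "balanced":
        if n & (n - 1) != 0:
            raise InvalidParameterError("balanced tree requires n_pops a power of two")
        levels = int(np.log2(n))
        nodes = [TreeNode(name=p, height=0.0) for p in populations]
        for level in range(1, levels + 1):
            h = level / levels
            nxt = []
            for i in range(0, len(nodes), 2):
                parent = TreeNode(name="", height=h, children=[nodes[i], nodes[i + 1]])
                for c in parent.children:
                    c.branch_length = h - c.height
                nxt.append(parent)
            nodes = nxt
        root = nodes[0]
    else:
        raise InvalidParameterError(f"unknown tree kind {kind!r}")
    divergence = _divergence_from_tree(root, populations)
    return SyntheticWorld(tree=root, populations=populations, divergence=divergence, seed=int(seed))


def expected_mean_pairwise_divergence(params: SyntheticParams) -> float:
    """Analytic E[divergence] for a random tip pair under the coalescent tree."""
    return 2.0


# ---------------------------------------------------------------------------
# landmarks


def simulate_landmarks(
    world: SyntheticWorld, params: SyntheticParams
) -> tuple[list[LandmarkConfiguration], dict]:
    """Specimen landmark configurations plus the true population mean shapes.

    The root mean shape is a random configuration on a ~100 mm scale;
    along each branch every raw coordinate performs Brownian motion with
    variance ``brownian_rate`` per unit time. Specimens add isotropic
    N(0, noise_sd^2) coordinate noise around their population mean.
    """
    rng = _substream(world.seed, _OFFSET_LANDMARKS)
    p = params.n_landmarks
    base = rng.normal(0.0, 30.0, size=(p, 3)) + 100.0  # cranium-scale raw coords

    means: dict = {}

    def descend(node: TreeNode, shape: np.ndarray) -> None:
        for child in node.children:
            step_sd = np.sqrt(params.brownian_rate * child.branch_length)
            child_shape = shape + rng.normal(0.0, 1.0, size=(p, 3)) * step_sd
            if child.is_leaf:
                means[child.name] = child_shape
            else:
                descend(child, child_shape)

    if world.tree.is_leaf:
        means[world.tree.name] = base
    else:
        descend(world.tree, base)

    configs = []
    for pop in world.populations:
        for k in range(params.n_specimens_per_pop):
            coords = means[pop] + rng.normal(0.0, params.noise_sd, size=(p, 3))
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{pop}_s{k:03d}", population_id=pop, coords=coords
                )
            )
    return configs, means


# ---------------------------------------------------------------------------
# word lists


def _random_word(rng: np.random.Generator, alphabet: str) -> str:
    length = int(rng.integers(2, 7))  # ASJP-like short words, lengths 2-6
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def simulate_wordlists(
    world: SyntheticWorld,
    params: SyntheticParams,
    concept_count: int = 40,
    alphabet: str = ASJP_ALPHABET,
) -> tuple[dict, dict]:
    """Word lists per population plus true cognacy class labels.

    A random root list evolves along each branch: every concept is
    replaced by a fresh random word (new cognate class) with probability
    1 - exp(-replacement_rate * t); surviving words substitute each
    segment independently with probability
    1 - exp(-substitution_rate * t). Returns ``(doculects, cognacy)``
    where ``cognacy[pop][concept]`` is an integer cognate class.
    """
    if not alphabet:
        raise InvalidParameterError("alphabet must be non-empty")
    if not (1 <= concept_count <= len(CONCEPTS)):
        raise InvalidParameterError(f"concept_count must be in 1..{len(CONCEPTS)}")
    rng = _substream(world.seed, _OFFSET_WORDS)
    concepts = CONCEPTS[:concept_count]
    next_class = [concept_count]  # root classes are 0..concept_count-1

    root_words = {c: _random_word(rng, alphabet) for c in concepts}
    root_classes = {c: i for i, c in enumerate(concepts)}

    doculects: dict = {}
    cognacy: dict = {}

    def descend(node: TreeNode, words: dict, classes: dict) -> None:
        for child in node.children:
            t = child.branch_length
            p_replace = 1.0 - np.exp(-params.cognate_replacement_rate * t)
            p_subst = 1.0 - np.exp(-params.sound_substitution_rate * t)
            child_words = {}
            child_classes = {}
            for c in concepts:
                if rng.random() < p_replace:
                    child_words[c] = _random_word(rng, alphabet)
                    child_classes[c] = next_class[0]
                    next_class[0] += 1
                else:
                    word = list(words[c])
                    for k in range(len(word)):
                        if rng.random() < p_subst:
                            word[k] = alphabet[int(rng.integers(0, len(alphabet)))]
                    child_words[c] = "".join(word)
                    child_classes[c] = classes[c]
            if child.is_leaf:
                doculects[child.name] = Doculect(
                    name=child.name,
                    classification=f"SYNTH.{child.name.upper()}",
                    words={c: [w] for c, w in child_words.items()},
                )
                cognacy[child.name] = child_classes
            else:
                descend(child, child_words, child_classes)

    if world.tree.is_leaf:
        doculects[world.tree.name] = Doculect(
            name=world.tree.name, words={c: [w] for c, w in root_words.items()}
        )
        cognacy[world.tree.name] = root_classes
    else:
        descend(world.tree, root_words, root_classes)
    return doculects, cognacy


def expected_noncognate_fraction(rate: float, divergence: float) -> float:
    """Closed-form probability a concept is non-cognate between two tips."""
    return 1.0 - np.exp(-rate * divergence)


# ---------------------------------------------------------------------------
# geography


def simulate_geography(
    world: SyntheticWorld,
    params: SyntheticParams,
    lat: float = 10.0,
    lon_start: float = 5.0,
    lon_span: float = 140.0,
    lat_jitter_deg: float = 0.0,
) -> tuple[dict, float]:
    """Place populations along a west-to-east corridor ordered by tree traversal.

    Adjacent tips (in leaf order) are spaced proportionally to their tree
    distance, so geodesic separation grows with divergence. Continents are
    assigned by longitude relative to the Cairo and Phnom Penh waypoint
    meridians (Africa / Asia / Australia), which exercises waypoint
    routing in downstream G matrices. Returns the coordinates and the
    achieved Spearman correlation between routed geographic distance and
    tree divergence.
    """
    rng = _substream(world.seed, _OFFSET_GEO)
    order = world.leaf_order()
    div = world.divergence
    gaps = [div.loc[order[i], order[i + 1]] for i in range(len(order) - 1)]
    positions = np.concatenate([[0.0], np.cumsum(gaps)])
    if positions[-1] > 0:
        positions = positions / positions[-1] * lon_span
    lons = lon_start + positions
    lats = lat + rng.normal(0.0, 1.0, size=len(order)) * lat_jitter_deg

    def continent(lon: float) -> str:
        if lon < 31.0:
            return "Africa"
        if lon < 105.0:
            return "Asia"
        return "Australia"

    points = {
        name: GeoPoint(float(np.clip(la, -89.0, 89.0)), float(lo), continent(lo))
        for name, la, lo in zip(order, lats, lons)
    }
    # achieved correlation is measured on the direct great-circle geodesic
    # (the quantity this placement controls); waypoint routing happens later
    n = len(world.populations)
    g = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = world.populations[i], world.populations[j]
            g[i, j] = g[j, i] = great_circle(
                points[a], points[b], params.sphere_radius_km
            )
    iu = np.triu_indices(n, k=1)
    rho = float(
        spearmanr(g[iu], div.loc[world.populations, world.populations].to_numpy()[iu]).statistic
    )
    return points, rho


# ---------------------------------------------------------------------------
# the whole-configuration partition scheme used for synthetic worlds


def default_partitions(p: int = 32) -> dict:
    """Whole/face/neurocranium/temporal partitions for a p-landmark scheme.

    For the canonical p=32 layout, landmarks 0-5 are midline and 6-31 form
    13 bilateral pairs; the subsets have the conventional sizes (face 13,
    neurocranium 8, temporal 13) and, as in real cranial schemes, share a
    few boundary landmarks. Other p get contiguous thirds.
    """
    if p < 12:
        raise InvalidParameterError("partition scheme needs p >= 12")
    midline = tuple(range(6))
    n_pairs = (p - 6) // 2
    pairs = tuple((6 + 2 * k, 7 + 2 * k) for k in range(n_pairs))
    whole = LandmarkPartition(
        name="whole", indices=tuple(range(p)), bilateral_pairs=pairs, midline=midline
    )
    if p == 32:
        face = LandmarkPartition(
            name="face", indices=(0, 1, 2, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15)
        )
        neuro = LandmarkPartition(
            name="neurocranium", indices=(3, 4, 16, 17, 18, 19, 20, 21)
        )
        temporal = LandmarkPartition(
            name="temporal", indices=(5, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31)
        )
    else:
        third = p // 3
        face = LandmarkPartition(name="face", indices=tuple(range(0, third + 1)))
        neuro = LandmarkPartition(
            name="neurocranium", indices=tuple(range(third, 2 * third + 1))
        )
        temporal = LandmarkPartition(name="temporal", indices=tuple(range(2 * third, p)))
    return {"whole": whole, "face": face, "neurocranium": neuro, "temporal": temporal}


# ---------------------------------------------------------------------------
# fixture bundle


def write_fixture_bundle(outdir, params: SyntheticParams, seed: int) -> dict:
    """Simulate a world and write TPS, ASJP, coordinate, and divergence files."""
    from pathlib import Path

    from cranolex.geography import write_coordinates_csv
    from cranolex.lexical import write_asjp
    from cranolex.morphometrics import write_tps

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    world = simulate_tree(params, seed)
    configs, means = simulate_landmarks(world, params)
    doculects, cognacy = simulate_wordlists(world, params)
    points, rho = simulate_geography(world, params)

    write_tps(configs, out / "landmarks.tps")
    write_asjp([doculects[p] for p in world.populations], out / "wordlists.asjp")
    write_coordinates_csv(points, out / "coordinates.csv")
    world.divergence.to_csv(out / "divergence.csv")
    (out / "tree.nwk").write_text(world.tree.newick() + "\n")
    return {
        "world": world,
        "landmarks": configs,
        "true_means": means,
        "doculects": doculects,
        "cognacy": cognacy,
        "geography": points,
        "geo_divergence_spearman": rho,
    }
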