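"""End-to-end orchestration: data (synthetic or user files) to result tables.

``run_all`` drives the full analysis: GPA on the whole-cranium landmark
set, post-GPA partitioning, bootstrap PCA component selection, pairwise
P_ST per partition, linguistic distances L, routed geographic distances G,
and the inferential layer — Mantel correlations of each P_ST partition
with L (table 1) and with G (table 2), partial Mantel of P_ST with L
controlling for G (table 3), and a Dow-Cheverud grid comparing partitions
against L, plain below the diagonal and G-controlled above (table 4) —
with Bonferroni corrections over the three cranial subsets.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cranolex import geography, lexical, matrix_stats, morphometrics, pst, synthetic
from cranolex.errors import FormatError, InvalidParameterError

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets off the analysis seed
_OFFSET_WORLD = 0
_OFFSET_BOOT = 11
_OFFSET_PERM = 23
_SEED_MOD = 2**31


def _stage_seed(seed: int, offset: int) -> int:
    return (int(seed) + offset) % _SEED_MOD


@dataclass
class AnalysisConfig:
    """Knobs of the full analysis; defaults match the published protocol."""

    h2: float = 0.3
    n_perm: int = 10000
    n_boot: int = 10000
    alpha: float = 0.05
    k_models: int = 3
    candidate_radius_km: float = 500.0
    seed: int = 0
    synthetic_params: synthetic.SyntheticParams = field(
        default_factory=synthetic.SyntheticParams
    )
    # optional user inputs; when None the synthetic generator supplies data
    landmarks_path: str | None = None
    wordlists_path: str | None = None
    coordinates_path: str | None = None
    weights_path: str | None = None
    weight_mode: str = "estimate"  # "estimate" (from synthetic cognates) or "uniform"

    def digest(self) -> str:
        payload = {
            k: (v if isinstance(v, (int, float, str, type(None))) else repr(v))
            for k, v in self.__dict__.items()
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    tables: dict  # name -> DataFrame
    matrices: dict  # name -> DataFrame (PST per partition, L, G, divergence)
    retained: dict  # partition -> retained component count
    corrections: dict
    provenance: dict


def read_square_matrix(path, labels: list | None = None) -> pd.DataFrame:
    """Read a labelled square CSV, validating symmetry and labels.

    With ``labels`` the matrix is returned reordered to that label order.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels differ")
    v = df.to_numpy(float)
    if not np.allclose(v, v.T, atol=1e-9, rtol=0.0):
        raise FormatError(f"{path}: matrix is not symmetric to 1e-9")
    if labels is not None:
        missing = set(map(str, labels)) - set(df.index)
        if missing:
            raise FormatError(f"{path}: labels {sorted(missing)} absent")
        df = df.loc[list(map(str, labels)), list(map(str, labels))]
    return df


def write_square_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path)


# ---------------------------------------------------------------------------
# stage runners


def _morphometrics_stage(configs, partitions, config: AnalysisConfig):
    whole = partitions["whole"]
    complete = [
        morphometrics.impute_bilateral(c, whole) if c.missing_mask.any() else c
        for c in configs
    ]
    aligned = morphometrics.gpa(complete)
    pst_matrices = {}
    retained = {}
    boot_seed = _stage_seed(config.seed, _OFFSET_BOOT)
    for name, part in partitions.items():
        subset = morphometrics.subset_partition(aligned, part)
        solution = morphometrics.select_components(
            subset, n_boot=config.n_boot, seed=boot_seed
        )
        t = max(solution.retained or 0, 1)  # P_ST needs at least one trait
        solution.retained = t
        retained[name] = t
        scores = morphometrics.retained_scores(subset, solution)
        pops = pst.scores_by_population(scores)
        options = pst.PstOptions(h2=config.h2)
        pst_matrices[name] = pst.pairwise_pst(pops, options).to_dataframe()
    return pst_matrices, retained


def _lexical_stage(doculects_by_pop: dict, config: AnalysisConfig, cognacy: dict | None):
    if config.weights_path:
        w = lexical.read_weight_matrix(config.weights_path)
    elif config.weight_mode == "estimate" and cognacy:
        w = _weights_from_cognates(doculects_by_pop, cognacy, config.seed)
    else:
        w = lexical.uniform_weights()
    candidates = {p: list(ds) for p, ds in doculects_by_pop.items()}
    l_matrix = lexical.population_distance_matrix(candidates, w)
    return l_matrix, w


def _weights_from_cognates(doculects_by_pop: dict, cognacy: dict, seed: int):
    """Log-odds weights trained on the world's true cognate pairs."""
    pops = list(doculects_by_pop)
    related, background = [], []
    rng = np.random.default_rng(_stage_seed(seed, 5))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            da = doculects_by_pop[pops[i]][0]
            db = doculects_by_pop[pops[j]][0]
            shared = sorted(da.concepts() & db.concepts())
            for c in shared:
                if cognacy[pops[i]].get(c) == cognacy[pops[j]].get(c):
                    related.append((da.words[c][0], db.words[c][0]))
            # background: cross-concept pairs, matched in number to related
            for _ in range(2):
                c1, c2 = rng.choice(shared, size=2, replace=False)
                if c1 != c2:
                    background.append((da.words[c1][0], db.words[c2][0]))
    if not related or not background:
        return lexical.uniform_weights()
    return lexical.estimate_weights(related, background, n_iter=2)


def _stats_stage(pst_matrices: dict, l_matrix, g_matrix, config: AnalysisConfig):
    seed = _stage_seed(config.seed, _OFFSET_PERM)
    partition_names = list(pst_matrices)
    subset_names = [n for n in partition_names if n != "whole"]

    rows1, rows2, rows3 = [], [], []
    for name in partition_names:
        m1 = matrix_stats.mantel(pst_matrices[name], l_matrix, config.n_perm, seed)
        m2 = matrix_stats.mantel(pst_matrices[name], g_matrix, config.n_perm, seed)
        m3 = matrix_stats.partial_mantel(
            pst_matrices[name], l_matrix, g_matrix, config.n_perm, seed
        )
        rows1.append({"measure": name, "r": m1.r, "p": m1.p_two_tailed})
        rows2.append({"measure": name, "r": m2.r, "p": m2.p_two_tailed})
        rows3.append({"measure": name, "r": m3.r, "p": m3.p_two_tailed})
    ml_g = matrix_stats.mantel(l_matrix, g_matrix, config.n_perm, seed)
    rows2.append({"measure": "L", "r": ml_g.r, "p": ml_g.p_two_tailed})

    table1 = pd.DataFrame(rows1)
    table2 = pd.DataFrame(rows2)
    table3 = pd.DataFrame(rows3)

    # Dow-Cheverud grid: below diagonal plain, above diagonal controlled for G
    grid_r = pd.DataFrame(np.nan, index=partition_names, columns=partition_names)
    grid_p = grid_r.copy()
    for a in partition_names:
        for b in partition_names:
            if a == b:
                continue
            controlled = partition_names.index(a) < partition_names.index(b)
            res = matrix_stats.dow_cheverud(
                pst_matrices[b],
                pst_matrices[a],
                l_matrix,
                control=g_matrix if controlled else None,
                n_perm=config.n_perm,
                seed=seed,
            )
            grid_r.loc[a, b] = res.r
            grid_p.loc[a, b] = res.p_two_tailed

    corrections = {}
    for tname, table in (("table1", table1), ("table2", table2), ("table3", table3)):
        sub = table[table["measure"].isin(subset_names)]
        ps = sub["p"].tolist()
        corrections[tname] = {
            "multiple": matrix_stats.bonferroni(
                ps, "multiple", k=config.k_models, alpha=config.alpha
            ),
            "sequential": matrix_stats.bonferroni(
                ps, "sequential", k=config.k_models, alpha=config.alpha
            ),
        }

    tables = {
        "table1_pst_vs_l": table1,
        "table2_vs_g": table2,
        "table3_partial_pst_l_given_g": table3,
        "table4_dow_cheverud_r": grid_r,
        "table4_dow_cheverud_p": grid_p,
    }
    return tables, corrections


# ---------------------------------------------------------------------------
# entry point


def run_all(config: AnalysisConfig) -> ResultsBundle:
    """Execute every stage and return the populated results bundle."""
    params = config.synthetic_params
    cognacy = None
    if config.landmarks_path:
        if str(config.landmarks_path).endswith(".tps"):
            configs = morphometrics.read_tps(config.landmarks_path)
        else:
            configs = morphometrics.read_landmarks_csv(config.landmarks_path)
        doculects = lexical.parse_asjp(config.wordlists_path)
        doculects_by_pop = _match_doculects(doculects, config)
        points = geography.read_coordinates_csv(config.coordinates_path)
        divergence = None
        p = configs[0].n_landmarks
    else:
        logger.info("no input paths given: generating a synthetic world (seed=%d)", config.seed)
        world = synthetic.simulate_tree(params, _stage_seed(config.seed, _OFFSET_WORLD))
        configs, _ = synthetic.simulate_landmarks(world, params)
        doculects_map, cognacy = synthetic.simulate_wordlists(world, params)
        doculects_by_pop = {p: [doculects_map[p]] for p in world.populations}
        points, _ = synthetic.simulate_geography(world, params)
        divergence = world.divergence
        p = params.n_landmarks

    partitions = synthetic.default_partitions(p)
    pst_matrices, retained = _morphometrics_stage(configs, partitions, config)
    l_matrix, weights = _lexical_stage(doculects_by_pop, config, cognacy)
    g_matrix = geography.distance_matrix(points)

    labels = sorted(
        set(l_matrix.columns) & set(g_matrix.columns) & set(pst_matrices["whole"].columns)
    )
    if len(labels) < 3:
        raise InvalidParameterError("fewer than 3 populations shared across inputs")
    pst_matrices = {k: v.loc[labels, labels] for k, v in pst_matrices.items()}
    l_matrix = l_matrix.loc[labels, labels]
    g_matrix = g_matrix.loc[labels, labels]

    tables, corrections = _stats_stage(pst_matrices, l_matrix, g_matrix, config)
    matrices = {f"pst_{k}": v for k, v in pst_matrices.items()}
    matrices["L"] = l_matrix
    matrices["G"] = g_matrix
    if divergence is not None:
        matrices["true_divergence"] = divergence.loc[labels, labels]

    return ResultsBundle(
        tables=tables,
        matrices=matrices,
        retained=retained,
        corrections=corrections,
        provenance={
            "config_digest": config.digest(),
            "seed": config.seed,
            "n_populations": len(labels),
            "populations": labels,
        },
    )


def _match_doculects(doculects, config: AnalysisConfig):
    """Group parsed doculects into per-population candidate sets by name prefix."""
    by_pop: dict = {}
    for d in doculects:
        by_pop.setdefault(d.name.split("__")[0], []).append(d)
    return by_pop


def save_bundle(bundle: ResultsBundle, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in bundle.tables.items():
        table.to_csv(out / f"{name}.csv", index=name.startswith("table4"))
    for name, matrix in bundle.matrices.items():
        write_square_matrix(matrix, out / f"matrix_{name}.csv")
    (out / "provenance.json").write_text(json.dumps(bundle.provenance, indent=2) + "\n")
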