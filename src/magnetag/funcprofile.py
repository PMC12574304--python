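"""Comparative functional genomics across fungal ecological lifestyles.

Per-genome annotation counting (CAZymes, lipases, proteases, transporters,
small secreted proteins), CAZy-family substrate classification into plant
vs microbial cell-wall degrading enzymes, pathway-completeness scoring for
the hallmark capabilities missing from Glomeromycotina genomes, and
Kruskal-Wallis + Dunn post-hoc lifestyle comparison with a compact letter
display.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "LIFESTYLES",
    "TRANSPORTER_SUBSTRATES",
    "PCWDE_GROUPS",
    "MCWDE_GROUPS",
    "SubstrateMap",
    "PathwayDef",
    "PathwayRole",
    "GroupTestResult",
    "load_annotations",
    "load_lifestyles",
    "load_substrate_map",
    "load_pathway_defs",
    "default_substrate_map",
    "default_pathway_defs",
    "count_categories",
    "classify_substrates",
    "pathway_completeness",
    "pathway_completeness_table",
    "genome_id_sets",
    "count_transporter_substrates",
    "group_compare",
    "dunn_test",
    "compact_letter_display",
]

CATEGORIES = ("CAZyme", "lipase", "protease", "transporter", "SSP")
LIFESTYLES = ("G-AMF", "ECM", "ERM", "OCM", "SAP", "PAT", "PAR", "END", "LIC", "MIX")
TRANSPORTER_SUBSTRATES = ("phosphate", "calcium", "copper", "nitrate", "ammonium",
                          "glycine", "other")
PCWDE_GROUPS = frozenset({"cellulose", "hemicellulose", "lignin", "pectin"})
MCWDE_GROUPS = frozenset({"chitin", "glycan", "mannan", "peptidoglycan"})


# ---------------------------------------------------------------------------
# Tables and configs


def load_annotations(path) -> pd.DataFrame:
    """Annotation TSV: genome, protein, category[, cazy_family, ec_numbers, substrate].

    ec_numbers are semicolon-joined.  Validates the category vocabulary,
    the family-iff-CAZyme rule, and (genome, protein, category) uniqueness.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return validate_annotations(df)


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    need = {"genome", "protein", "category"}
    if not need <= set(df.columns):
        raise ValueError(f"annotation table must have columns {sorted(need)}")
    for col in ("cazy_family", "ec_numbers", "substrate"):
        if col not in df.columns:
            df[col] = ""
    df = df.fillna("")
    bad = df.loc[~df["category"].isin(CATEGORIES)]
    if len(bad):
        raise ValueError(
            f"unknown categories {sorted(bad['category'].unique())} at rows "
            f"{bad.index[:5].tolist()}; vocabulary: {CATEGORIES}"
        )
    dup = df.duplicated(subset=["genome", "protein", "category"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["genome", "protein", "category"]].head()
        raise ValueError(f"duplicate (genome, protein, category) rows:\n{offenders}")
    caz = df["category"] == "CAZyme"
    if (caz & (df["cazy_family"] == "")).any():
        raise ValueError("CAZyme rows must carry a cazy_family")
    if (~caz & (df["cazy_family"] != "")).any():
        raise ValueError("cazy_family only allowed on CAZyme rows")
    return df


def load_lifestyles(path) -> pd.Series:
    """Lifestyle TSV ``genome<TAB>lifestyle`` validated against the vocabulary."""
    df = pd.read_csv(path, sep="\t", header=None, names=["genome", "lifestyle"], dtype=str)
    bad = df.loc[~df["lifestyle"].isin(LIFESTYLES)]
    if len(bad):
        raise ValueError(
            f"unknown lifestyle labels {sorted(bad['lifestyle'].unique())} at rows "
            f"{(bad.index + 1).tolist()[:5]}; vocabulary: {list(LIFESTYLES)}"
        )
    return df.set_index("genome")["lifestyle"]


@dataclass
class SubstrateMap:
    """CAZy family -> substrate groups, partitioned into plant (PCWDE) and
    microbial (MCWDE) cell-wall sides."""

    families: dict[str, frozenset[str]]

    def groups_of(self, family: str) -> frozenset[str]:
        return self.families.get(family, frozenset())

    @classmethod
    def from_json(cls, path_or_obj) -> "SubstrateMap":
        obj = path_or_obj
        if not isinstance(obj, dict):
            obj = json.load(open(obj))
        fams = {f: frozenset(gs) for f, gs in obj["families"].items()}
        return cls(families=fams)


def load_substrate_map(path=None) -> SubstrateMap:
    if path is None:
        return default_substrate_map()
    return SubstrateMap.from_json(path)


def default_substrate_map() -> SubstrateMap:
    with resources.files("magnetag.data").joinpath("substrate_map.json").open() as fh:
        return SubstrateMap.from_json(json.load(fh))


@dataclass(frozen=True)
class PathwayRole:
    name: str
    any_of: tuple[tuple[str, ...], ...]  # alternatives; each a conjunction of ids


@dataclass(frozen=True)
class PathwayDef:
    name: str
    roles: tuple[PathwayRole, ...]

    def __post_init__(self):
        if not self.roles:
            raise ValueError(f"pathway {self.name!r} has no roles")
        for r in self.roles:
            if not r.any_of or any(not alt for alt in r.any_of):
                raise ValueError(f"role {r.name!r} has empty satisfier list")


def load_pathway_defs(path=None) -> list[PathwayDef]:
    if path is None:
        return default_pathway_defs()
    obj = json.load(open(path))
    return _defs_from_obj(obj)


def default_pathway_defs() -> list[PathwayDef]:
    with resources.files("magnetag.data").joinpath("pathways.json").open() as fh:
        return _defs_from_obj(json.load(fh))


def _defs_from_obj(obj) -> list[PathwayDef]:
    defs = []
    for p in obj["pathways"]:
        roles = tuple(
            PathwayRole(r["name"], tuple(tuple(alt) for alt in r["any_of"]))
            for r in p["roles"]
        )
        defs.append(PathwayDef(p["name"], roles))
    return defs


# ---------------------------------------------------------------------------
# Counting


def count_categories(table: pd.DataFrame) -> pd.DataFrame:
    """Per-genome counts per category plus a ``total_annotated`` column."""
    table = validate_annotations(table.copy())
    counts = (
        table.groupby(["genome", "category"], sort=True).size().unstack(fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    counts.columns.name = None
    counts["total_annotated"] = counts.sum(axis=1)
    return counts


def classify_substrates(table: pd.DataFrame, smap: SubstrateMap | None = None,
                        side_counting: str = "unique-protein") -> pd.DataFrame:
    """Per-genome substrate-group copy counts and PCWDE/MCWDE totals.

    A CAZyme in k groups contributes one copy to each group.  Side totals
    (PCWDE, MCWDE) default to unique proteins — a protein hitting several
    groups on one side counts once there; ``side_counting='per-group'``
    sums the group counts instead.  Families absent from the map are
    tallied under ``unclassified``.
    """
    if smap is None:
        smap = default_substrate_map()
    if side_counting not in ("unique-protein", "per-group"):
        raise ValueError("side_counting must be 'unique-protein' or 'per-group'")
    caz = table.loc[table["category"] == "CAZyme"]
    groups = sorted(PCWDE_GROUPS | MCWDE_GROUPS) + ["other", "unclassified"]
    out = {}
    unmapped: set[str] = set()
    for genome, sub in caz.groupby("genome"):
        row = dict.fromkeys(groups, 0)
        pcwde = mcwde = 0
        for _, rec in sub.iterrows():
            gs = smap.groups_of(rec["cazy_family"])
            if not gs:
                row["unclassified"] += 1
                unmapped.add(rec["cazy_family"])
                continue
            for g in gs:
                row[g if g in row else "other"] += 1
            if side_counting == "unique-protein":
                pcwde += bool(gs & PCWDE_GROUPS)
                mcwde += bool(gs & MCWDE_GROUPS)
        if side_counting == "per-group":
            pcwde = sum(row[g] for g in PCWDE_GROUPS)
            mcwde = sum(row[g] for g in MCWDE_GROUPS)
        row["PCWDE"], row["MCWDE"] = pcwde, mcwde
        out[genome] = row
    if unmapped:
        log.info("families not in substrate map (counted unclassified): %s",
                 sorted(unmapped))
    cols = groups + ["PCWDE", "MCWDE"]
    return pd.DataFrame(out).T.reindex(columns=cols, fill_value=0).fillna(0).astype(int)


def count_transporter_substrates(table: pd.DataFrame) -> pd.DataFrame:
    """Per-genome transporter counts by substrate; unknown substrates -> other."""
    tr = table.loc[table["category"] == "transporter"].copy()
    tr["substrate"] = tr["substrate"].where(
        tr["substrate"].isin(TRANSPORTER_SUBSTRATES), "other"
    ).replace("", "other")
    counts = (
        tr.groupby(["genome", "substrate"]).size().unstack(fill_value=0)
        .reindex(columns=list(TRANSPORTER_SUBSTRATES), fill_value=0)
    )
    counts.columns.name = None
    return counts


# ---------------------------------------------------------------------------
# Pathway completeness


def _normalise_ec(ec: str) -> str:
    return ec.strip()


def _id_present(identifier: str, id_set: set[str]) -> bool:
    """Exact match, with trailing '-' components in either side as wildcards."""
    ident = _normalise_ec(identifier)
    if ident in id_set:
        return True
    if "." in ident:
        want = ident.split(".")
        for have in id_set:
            parts = have.split(".")
            if len(parts) != len(want):
                continue
            if all(w == p or w == "-" or p == "-" for w, p in zip(want, parts)):
                return True
    return False


def genome_id_sets(table: pd.DataFrame) -> dict[str, set[str]]:
    """Per-genome set of EC numbers and CAZy family codes."""
    sets: dict[str, set[str]] = {}
    for _, rec in table.iterrows():
        s = sets.setdefault(rec["genome"], set())
        if rec.get("cazy_family"):
            s.add(rec["cazy_family"])
        for ec in str(rec.get("ec_numbers", "")).split(";"):
            ec = _normalise_ec(ec)
            if ec:
                s.add(ec)
    return sets


@dataclass
class PathwayScore:
    pathway: str
    complete: bool
    fraction: float
    missing_roles: list[str]


def pathway_completeness(id_set: set[str], defs: list[PathwayDef] | None = None) -> list[PathwayScore]:
    """Score each pathway: complete iff every role has a fully satisfied
    alternative; fraction = satisfied roles / roles."""
    if defs is None:
        defs = default_pathway_defs()
    if not defs:
        raise ValueError("empty pathway definition list")
    scores = []
    for pd_ in defs:
        missing = []
        for role in pd_.roles:
            ok = any(all(_id_present(i, id_set) for i in alt) for alt in role.any_of)
            if not ok:
                missing.append(role.name)
        n = len(pd_.roles)
        scores.append(PathwayScore(pd_.name, not missing, (n - len(missing)) / n, missing))
    return scores


def pathway_completeness_table(table: pd.DataFrame,
                               defs: list[PathwayDef] | None = None) -> pd.DataFrame:
    """Per-genome pathway completeness fractions (rows: genome, cols: pathway)."""
    sets = genome_id_sets(table)
    rows = {
        g: {s.pathway: s.fraction for s in pathway_completeness(ids, defs)}
        for g, ids in sets.items()
    }
    return pd.DataFrame(rows).T.sort_index()


# ---------------------------------------------------------------------------
# Group comparison


def dunn_test(values: pd.Series, groups: pd.Series, adjust: str = "fdr_bh") -> pd.DataFrame:
    """Dunn's post-hoc test on pooled ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)) over tied groups; two-sided p values
    adjusted across all pairs.  Returns a symmetric adjusted-p matrix.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    names = sorted(pd.unique(g).tolist())
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    N = len(v)
    ranks = stats.rankdata(v)
    mean_rank = {name: ranks[g == name].mean() for name in names}
    n = {name: int((g == name).sum()) for name in names}
    _, tie_counts = np.unique(v, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / n[a] + 1.0 / n[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        raw.append(2.0 * stats.norm.sf(abs(z)))
    adj = multipletests(raw, method=adjust)[1] if pairs else []
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (a, b), p in zip(pairs, adj):
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def compact_letter_display(pairwise_p: pd.DataFrame, medians: pd.Series,
                           alpha: float = 0.05) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different (adjusted
    p >= alpha).  Groups are processed in descending median order so the
    letter 'a' attaches to the highest-valued clique.
    """
    names = sorted(pairwise_p.index, key=lambda k: (-medians[k], k))
    # Piepho insert-and-absorb: start with one letter covering everything,
    # split it at each significant pair, absorb sets contained in others.
    letters: list[set[str]] = [set(names)]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if pairwise_p.loc[a, b] >= alpha:
                continue
            new: list[set[str]] = []
            for s in letters:
                if a in s and b in s:
                    new.append(s - {a})
                    new.append(s - {b})
                else:
                    new.append(s)
            # absorb duplicates and subsets
            new.sort(key=len, reverse=True)
            letters = []
            for s in new:
                if s and not any(s <= t for t in letters):
                    letters.append(s)
    pruned = sorted(letters, key=lambda s: min(names.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, list[str]] = {g: [] for g in names}
    for letter, s in zip(alphabet, pruned):
        for g in names:
            if g in s:
                out[g].append(letter)
    return {g: "".join(ls) for g, ls in out.items()}


@dataclass
class GroupTestResult:
    """Kruskal-Wallis omnibus plus Dunn pairwise letters for one metric."""

    metric: str
    h_statistic: float
    p_value: float
    dunn_p: pd.DataFrame | None
    letters: dict[str, str]
    group_medians: pd.Series
    group_n: pd.Series
    alpha_kw: float
    alpha_dunn: float

    def summary(self) -> str:
        lines = [
            f"Kruskal-Wallis on {self.metric}: H = {self.h_statistic:.3f}, "
            f"p = {self.p_value:.3g}"
            + ("" if self.p_value < self.alpha_kw else
               f" (not significant at alpha={self.alpha_kw})"),
            f"{'lifestyle':<10}{'n':>4}{'median':>10}  letters",
        ]
        for g in self.group_medians.sort_values(ascending=False).index:
            lines.append(
                f"{g:<10}{self.group_n[g]:>4}{self.group_medians[g]:>10.1f}  "
                f"{self.letters.get(g, '')}"
            )
        return "\n".join(lines)


def group_compare(profiles: pd.DataFrame, lifestyles: pd.Series, metric: str,
                  alpha_kw: float = 0.01, alpha_dunn: float = 0.05,
                  adjust: str = "fdr_bh") -> GroupTestResult:
    """Compare one per-genome metric across ecological lifestyles.

    Kruskal-Wallis with tie correction on all groups with >= 2 members;
    when the omnibus test is significant at ``alpha_kw``, Dunn pairwise
    z-tests (adjusted) feed a compact letter display at ``alpha_dunn``.
    """
    if metric not in profiles.columns:
        raise ValueError(f"metric {metric!r} not in profiles "
                         f"(have {list(profiles.columns)})")
    joined = profiles[[metric]].join(lifestyles.rename("lifestyle"), how="inner").dropna()
    sizes = joined.groupby("lifestyle").size()
    keep = sizes[sizes >= 2].index
    joined = joined.loc[joined["lifestyle"].isin(keep)]
    if len(keep) < 2:
        raise ValueError("need >= 2 lifestyles with >= 2 genomes each")
    samples = [grp[metric].to_numpy(float) for _, grp in joined.groupby("lifestyle")]
    if np.ptp(np.concatenate(samples)) == 0:
        h, p = 0.0, 1.0  # identical values in every group: no evidence of difference
    else:
        h, p = stats.kruskal(*samples)
    medians = joined.groupby("lifestyle")[metric].median()
    ns = joined.groupby("lifestyle").size()
    if p < alpha_kw:
        dunn = dunn_test(joined[metric], joined["lifestyle"], adjust=adjust)
        letters = compact_letter_display(dunn, medians, alpha=alpha_dunn)
    else:
        dunn = None
        letters = {g: "a" for g in medians.index}
    return GroupTestResult(metric, float(h), float(p), dunn, letters, medians, ns,
                           alpha_kw, alpha_dunn)
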