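"""Post-search spectral-counting proteomics.

Stages, in pipeline order:

1. **Identification filtering** — keep peptides with E-value < 0.01;
   keep a protein only if it has at least two distinct retained peptides
   and the product of its unique peptides' E-values is below 1e-4.
2. **Protein grouping** — proteins sharing at least one retained peptide
   fall in the same group (connected components of the bipartite
   protein-peptide graph); a group member with at least one peptide
   specific to it (within the group) forms a subgroup, the quantifiable
   unit.
3. **Count assembly** — spectral counts of specific peptides are summed
   per subgroup per sample; peptides shared between subgroups are kept
   at a group-level row so no spectrum is counted twice.
4. **Differential abundance** — per protein, a Poisson GLM of counts on
   the group factor (log link, optional log-total-spectra offset), with
   a likelihood-ratio chi-square test of the group effect, followed by
   Benjamini-Hochberg adjustment across tested proteins and pairwise
   Student t contrasts with up/down direction calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import SchemaError, StatsPreconditionError

PEPTIDE_EVALUE_MAX = 0.01
PROTEIN_EVALUE_MAX = 1e-4
MIN_PEPTIDES = 2


def _normalize_proteins(value) -> frozenset[str]:
    if isinstance(value, str):
        parts = [p.strip() for p in value.split(";") if p.strip()]
    else:
        parts = [str(p) for p in value]
    if not parts:
        raise SchemaError("peptide row maps to no protein")
    return frozenset(parts)


def filter_identifications(
    peptides: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the identification filter to a long-format peptide table.

    Expects columns ``peptide, evalue, proteins`` (semicolon-separated
    accessions or an iterable) and optionally ``sample, spectra``.
    Duplicate (peptide, protein-set) evidence is collapsed to the best
    (minimum) E-value with a warning.

    Returns ``(retained_peptides, evidence)`` where ``retained_peptides``
    is the input restricted to peptides passing the E-value cut that map
    to at least one retained protein, with mappings restricted to
    retained proteins, and ``evidence`` is per-protein:
    ``n_peptides, evalue_product, retained``.
    """
    required = {"peptide", "evalue", "proteins"}
    missing = required - set(peptides.columns)
    if missing:
        raise SchemaError(f"peptide table missing columns: {sorted(missing)}")
    if (peptides["evalue"] <= 0).any():
        raise SchemaError("E-values must be positive")

    pep = peptides.copy()
    pep["proteins"] = pep["proteins"].map(_normalize_proteins)

    # peptide-level evidence: one E-value and protein set per sequence
    ev = pep.groupby("peptide").agg(evalue=("evalue", "min"), nvals=("evalue", "nunique"))
    if (ev["nvals"] > 1).any():
        dupes = ev.index[ev["nvals"] > 1].tolist()
        warnings.warn(
            f"peptides with conflicting E-values collapsed to the minimum: {dupes[:5]}",
            stacklevel=2,
        )
    prot_sets = pep.groupby("peptide")["proteins"].agg(lambda s: frozenset().union(*s))

    retained_peps = ev.index[ev["evalue"] < PEPTIDE_EVALUE_MAX]

    by_protein: dict[str, dict[str, float]] = {}
    for p in retained_peps:
        for acc in prot_sets[p]:
            by_protein.setdefault(acc, {})[p] = ev.loc[p, "evalue"]
    all_proteins = sorted(frozenset().union(*pep["proteins"]))
    rows = []
    retained_prots = set()
    for acc in all_proteins:
        peps = by_protein.get(acc, {})
        product = float(np.prod(list(peps.values()))) if peps else np.nan
        keep = len(peps) >= MIN_PEPTIDES and product < PROTEIN_EVALUE_MAX
        if keep:
            retained_prots.add(acc)
        rows.append(
            {
                "protein": acc,
                "n_peptides": len(peps),
                "evalue_product": product,
                "retained": keep,
            }
        )
    evidence = pd.DataFrame(rows).set_index("protein")

    keep_mask = pep["peptide"].isin(set(retained_peps)) & pep["proteins"].map(
        lambda s: bool(s & retained_prots)
    )
    retained = pep[keep_mask].copy()
    retained["proteins"] = retained["proteins"].map(lambda s: frozenset(s & retained_prots))
    return retained.reset_index(drop=True), evidence


@dataclass
class ProteinGroup:
    """Proteins connected through shared peptides.

    ``subgroups`` lists members with at least one peptide specific to
    them within the group — each subgroup stands for one distinguishable
    protein; ``specific_peptides`` maps each member to its specific
    peptide set (possibly empty).
    """

    group_id: str
    members: tuple[str, ...]
    subgroups: tuple[str, ...]
    specific_peptides: dict[str, frozenset[str]] = field(default_factory=dict)
    shared_peptides: frozenset[str] = frozenset()


def group_proteins(retained_peptides: pd.DataFrame) -> list[ProteinGroup]:
    """Partition retained proteins into shared-peptide groups.

    Two proteins sharing >= 1 retained peptide land in the same group
    (transitively).  Group ids are the lexicographically smallest member
    accession; groups are returned sorted by id.
    """
    pep_map: dict[str, frozenset[str]] = {}
    for _, row in retained_peptides.iterrows():
        prots = row["proteins"] if isinstance(row["proteins"], frozenset) else _normalize_proteins(row["proteins"])
        prev = pep_map.get(row["peptide"])
        pep_map[row["peptide"]] = prots if prev is None else prev | prots

    g = nx.Graph()
    for pep, prots in pep_map.items():
        g.add_node(("pep", pep))
        for acc in prots:
            g.add_node(("prot", acc))
            g.add_edge(("pep", pep), ("prot", acc))

    groups = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(n[1] for n in comp if n[0] == "prot"))
        if not members:
            continue
        peps_in_group = [n[1] for n in comp if n[0] == "pep"]
        specific: dict[str, set[str]] = {m: set() for m in members}
        shared: set[str] = set()
        for pep in peps_in_group:
            owners = pep_map[pep] & set(members)
            if len(owners) == 1:
                specific[next(iter(owners))].add(pep)
            else:
                shared.add(pep)
        subgroups = tuple(m for m in members if specific[m])
        groups.append(
            ProteinGroup(
                group_id=members[0],
                members=members,
                subgroups=subgroups,
                specific_peptides={m: frozenset(s) for m, s in specific.items()},
                shared_peptides=frozenset(shared),
            )
        )
    return sorted(groups, key=lambda gr: gr.group_id)


def assemble_counts(
    groups: Sequence[ProteinGroup],
    retained_peptides: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the spectral-count matrix from grouped evidence.

    Rows are subgroups (named by member accession); peptides shared
    between subgroup members contribute to a group-level row named
    ``<group_id>/shared`` instead of any subgroup, so counts are never
    double-assigned.  Samples whose total spectrum count is zero are
    dropped with a warning.

    Returns ``(counts, row_info)`` where ``row_info`` maps each row to
    its group, member and level (``subgroup`` / ``group``).
    """
    if not {"sample", "spectra"} <= set(retained_peptides.columns):
        raise SchemaError("retained peptide table needs 'sample' and 'spectra' columns")
    pep_to_row: dict[str, str] = {}
    row_info_rows = []
    for gr in groups:
        for m in gr.subgroups:
            row_info_rows.append(
                {"row": m, "group_id": gr.group_id, "member": m, "level": "subgroup"}
            )
            for pep in gr.specific_peptides[m]:
                pep_to_row[pep] = m
        if gr.shared_peptides:
            row = f"{gr.group_id}/shared"
            row_info_rows.append(
                {"row": row, "group_id": gr.group_id, "member": "", "level": "group"}
            )
            for pep in gr.shared_peptides:
                pep_to_row[pep] = row

    sub = retained_peptides[retained_peptides["peptide"].isin(pep_to_row)].copy()
    sub["row"] = sub["peptide"].map(pep_to_row)
    counts = (
        sub.pivot_table(index="row", columns="sample", values="spectra", aggfunc="sum", fill_value=0)
        .astype(int)
    )
    row_info = pd.DataFrame(row_info_rows).set_index("row")
    counts = counts.reindex(row_info.index, fill_value=0)

    empty = counts.columns[counts.sum(axis=0) == 0]
    if len(empty):
        warnings.warn(f"dropping samples with zero total spectra: {list(empty)}", stacklevel=2)
        counts = counts.drop(columns=empty)
    counts.index.name = "protein"
    counts.columns.name = "sample"
    return counts, row_info


def size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios per-sample size factors (geometric mean 1).

    For each sample, the median over proteins of the ratio of its count
    to the protein's geometric mean across samples, computed over
    proteins observed in every sample.  Unlike raw total spectra this is
    robust to a large asymmetric block of truly changing proteins, which
    would otherwise masquerade as run depth.  Falls back to normalized
    column totals when fewer than 10 proteins are complete.
    """
    arr = counts.to_numpy(float)
    complete = (arr > 0).all(axis=1)
    if complete.sum() >= 10:
        logc = np.log(arr[complete])
        ratios = logc - logc.mean(axis=1, keepdims=True)
        log_sf = np.median(ratios, axis=0)
    else:
        totals = arr.sum(axis=0)
        if (totals <= 0).any():
            raise StatsPreconditionError("cannot compute size factors: empty sample")
        log_sf = np.log(totals)
    log_sf = log_sf - log_sf.mean()
    return np.exp(log_sf)


def poisson_group_test(
    counts: pd.DataFrame,
    sample_groups: pd.Series | Mapping[str, str],
    offset: bool | str = True,
) -> pd.DataFrame:
    """Per-protein Poisson-GLM likelihood-ratio test of the group factor.

    Counts are regressed on the group label with a log link (fixed
    effects only; with a handful of samples per group a random term is
    not identifiable).  ``offset`` controls the library-size exposure
    term: ``True`` (default) uses log median-of-ratios size factors
    (:func:`size_factors`), ``"total"`` uses log total spectra per
    sample, and ``False`` fits the unadjusted model.  The group effect
    is tested by the deviance difference against the intercept-only
    model, chi-square with k-1 df.

    All-zero rows are reported with ``testable=False`` and NaN p-values,
    never p = 1.  An over-dispersion diagnostic (Pearson chi2 / residual
    df of the full model) is included per protein.
    """
    sample_groups = pd.Series(sample_groups)
    if not set(counts.columns) <= set(sample_groups.index):
        raise SchemaError("every count column needs a group label")
    labels = sample_groups.loc[counts.columns]
    group_names = sorted(labels.unique())
    k = len(group_names)
    if k < 2:
        raise StatsPreconditionError("need >= 2 groups")
    if (labels.value_counts() < 2).any():
        raise StatsPreconditionError("need >= 2 samples per group")

    x_full = pd.get_dummies(labels, drop_first=True, dtype=float)
    x_full = sm.add_constant(x_full.to_numpy())
    x_null = np.ones((len(labels), 1))
    if offset is True:
        off = np.log(size_factors(counts))
    elif offset == "total":
        off = np.log(counts.sum(axis=0).to_numpy(float))
    elif offset in (False, None):
        off = None
    else:
        raise SchemaError(f"offset must be True, 'total' or False, got {offset!r}")

    rows = []
    for prot, y in counts.iterrows():
        y = y.to_numpy(float)
        if y.sum() == 0:
            rows.append(
                {
                    "protein": prot,
                    "deviance": np.nan,
                    "df": k - 1,
                    "pvalue": np.nan,
                    "overdispersion": np.nan,
                    "testable": False,
                }
            )
            continue
        full = sm.GLM(y, x_full, family=sm.families.Poisson(), offset=off).fit()
        null = sm.GLM(y, x_null, family=sm.families.Poisson(), offset=off).fit()
        lrt = float(null.deviance - full.deviance)
        lrt = max(lrt, 0.0)
        p = float(stats.chi2.sf(lrt, k - 1))
        rows.append(
            {
                "protein": prot,
                "deviance": lrt,
                "df": k - 1,
                "pvalue": p,
                "overdispersion": float(full.pearson_chi2 / full.df_resid)
                if full.df_resid > 0
                else np.nan,
                "testable": True,
            }
        )
    res = pd.DataFrame(rows).set_index("protein")
    # BH family = tested proteins only; untestable rows keep NaN
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    return res


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Missing values propagate as NaN and do not count toward the family
    size; out-of-range p-values raise.
    """
    p = np.asarray(pvalues, float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise SchemaError("p-values must lie in [0, 1]")
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def pairwise_contrasts(
    counts: pd.DataFrame,
    sample_groups: pd.Series | Mapping[str, str],
    contrasts: Sequence[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    sqrt_transform: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sample Student t contrasts per protein with direction calls.

    Each contrast is an ordered pair ``(reference, alternative)``; the
    direction is ``up`` when the alternative group's mean count exceeds
    the reference (``down`` otherwise) and is reported only for
    significant proteins (p < alpha).  ``sqrt_transform`` applies a
    variance-stabilizing square root before testing (off by default:
    tests run on counts as given).  Comparisons with zero variance in
    both groups are untestable (NaN p).

    Returns ``(results, summary)``; ``summary`` tallies up/down counts
    per contrast.
    """
    sample_groups = pd.Series(sample_groups)
    labels = sample_groups.loc[counts.columns]
    names = sorted(labels.unique())
    if contrasts is None:
        contrasts = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    for ref, alt in contrasts:
        if ref not in set(labels) or alt not in set(labels):
            raise SchemaError(f"contrast ({ref!r}, {alt!r}) refers to an unknown group")

    data = np.sqrt(counts.to_numpy(float)) if sqrt_transform else counts.to_numpy(float)
    raw = counts.to_numpy(float)
    cols = {g: np.flatnonzero((labels == g).to_numpy()) for g in names}

    rows = []
    for ref, alt in contrasts:
        label = f"{alt} vs {ref}"
        a_idx, b_idx = cols[ref], cols[alt]
        for i, prot in enumerate(counts.index):
            a, b = data[i, a_idx], data[i, b_idx]
            mean_ref, mean_alt = float(raw[i, a_idx].mean()), float(raw[i, b_idx].mean())
            if np.var(a) == 0 and np.var(b) == 0:
                p, t = (np.nan, np.nan)
            else:
                t, p = stats.ttest_ind(b, a, equal_var=True)
            sig = bool(p < alpha) if not np.isnan(p) else False
            rows.append(
                {
                    "protein": prot,
                    "contrast": label,
                    "mean_ref": mean_ref,
                    "mean_alt": mean_alt,
                    "statistic": float(t) if not np.isnan(t) else np.nan,
                    "pvalue": float(p) if not np.isnan(p) else np.nan,
                    "significant": sig,
                    "direction": ("up" if mean_alt > mean_ref else "down") if sig else "",
                }
            )
    results = pd.DataFrame(rows)
    summary = (
        results[results["significant"]]
        .groupby("contrast")["direction"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["down", "up"], fill_value=0)
        .rename(columns={"down": "n_down", "up": "n_up"})
        .reset_index()
    )
    return results, summary
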