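"""Cell-type specificity annotation from nTPM expression profiles.

Each gene's nTPM values are normalized across all available cell types by
z-scoring on the log scale — equivalently, the log-ratio to the geometric
mean scaled by the log geometric SD.  A gene is enriched in a brain-related
cell type when its z-score there reaches the threshold (default 2.0); genes
enriched in two or more brain cell types are 'oligoMultiCell' when the
oligodendrocyte lineage (oligodendrocytes or OPCs) is involved and
'multiCell' otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd
import yaml

from .config import BRAIN_CELL_TYPES, OLIGO_LINEAGE
from .errors import InputError

# pseudocount added before logging: nTPM can be exactly 0; 0.1 is small
# relative to the conventional 1-nTPM detection cutoff
DEFAULT_EPS = 0.1

CATEGORIES = ("none", "single", "oligoMultiCell", "multiCell")


@dataclass(frozen=True)
class CellTypeVocabulary:
    """Cell-type universe with its brain-related and oligo-lineage subsets."""

    all_types: Tuple[str, ...]
    brain_related: FrozenSet[str]
    oligo_lineage: FrozenSet[str]

    def __post_init__(self):
        all_set = set(self.all_types)
        if not self.brain_related <= all_set:
            raise InputError("brain_related must be a subset of all_types")
        if not self.oligo_lineage <= self.brain_related:
            raise InputError("oligo_lineage must be a subset of brain_related")

    @classmethod
    def default(cls, cell_types: Iterable[str]) -> "CellTypeVocabulary":
        types = tuple(cell_types)
        brain = frozenset(t for t in types if t in BRAIN_CELL_TYPES)
        oligo = frozenset(t for t in types if t in OLIGO_LINEAGE)
        return cls(all_types=types, brain_related=brain, oligo_lineage=oligo)

    @classmethod
    def from_yaml(cls, path) -> "CellTypeVocabulary":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            all_types=tuple(raw["all_types"]),
            brain_related=frozenset(raw["brain_related"]),
            oligo_lineage=frozenset(raw["oligo_lineage"]),
        )

    def to_yaml(self, path) -> None:
        payload = {
            "all_types": list(self.all_types),
            "brain_related": sorted(self.brain_related),
            "oligo_lineage": sorted(self.oligo_lineage),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def geometric_zscores(values, eps: float = DEFAULT_EPS):
    """Z-scores of log(nTPM + eps): geometric-mean/SD normalization.

    z_c = (ln(x_c + eps) - mean ln(x + eps)) / sd ln(x + eps), with the
    sample (n-1) SD.  Accepts a 1-D vector (one gene) or a 2-D genes x
    cell-types frame/array and normalizes along cell types.  An all-equal
    row (zero SD) yields z = 0 everywhere, by convention.
    """
    arr = np.asarray(values, dtype=float)
    one_d = arr.ndim == 1
    if one_d:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise InputError("values must be 1-D or 2-D")
    if arr.shape[1] < 2:
        raise InputError("at least 2 cell types are required")
    if (arr < 0).any():
        raise InputError("nTPM values must be non-negative")
    logs = np.log(arr + eps)
    mean = logs.mean(axis=1, keepdims=True)
    sd = logs.std(axis=1, ddof=1, keepdims=True)
    # an all-equal row is degenerate (z = 0); tolerate float rounding of the mean
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    z = np.where(degenerate, 0.0, (logs - mean) / np.where(degenerate, 1.0, sd))
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(z, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(z[0], index=values.index)
    return z[0] if one_d else z


def classify(
    z: Mapping[str, float],
    vocab: CellTypeVocabulary,
    z_threshold: float = 2.0,
) -> Tuple[FrozenSet[str], str]:
    """Categorical enrichment call from per-cell-type z-scores.

    Only brain-related cell types can be enriched (a z at threshold in a
    peripheral type is ignored); ties at exactly the threshold count as
    enriched.  Returns (enriched types, category) with category in
    ``CATEGORIES``.
    """
    missing = [t for t in vocab.all_types if t not in z]
    if missing:
        raise InputError(f"z-scores missing for cell types: {missing}")
    enriched = frozenset(t for t in vocab.brain_related if z[t] >= z_threshold)
    if not enriched:
        category = "none"
    elif len(enriched) == 1:
        category = "single"
    elif enriched & vocab.oligo_lineage:
        category = "oligoMultiCell"
    else:
        category = "multiCell"
    return enriched, category


def build_calls(
    ntpm: pd.DataFrame,
    vocab: CellTypeVocabulary,
    z_threshold: float = 2.0,
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Specificity calls for every gene of a wide genes x cell-types matrix.

    Returns a DataFrame indexed like ``ntpm`` with columns ``category``,
    ``enriched_types`` (semicolon-joined) and one ``z_<cell type>`` column
    per cell type.
    """
    z = geometric_zscores(ntpm, eps=eps)
    rows = []
    for gene in ntpm.index:
        enriched, category = classify(z.loc[gene].to_dict(), vocab, z_threshold)
        rows.append(
            {
                "gene_symbol": gene,
                "category": category,
                "enriched_types": ";".join(sorted(enriched)),
            }
        )
    calls = pd.DataFrame(rows).set_index("gene_symbol")
    zcols = z.rename(columns=lambda c: f"z_{c}")
    return calls.join(zcols)


def annotate_scan(
    records: pd.DataFrame,
    calls: pd.DataFrame,
    vocab: CellTypeVocabulary,
    alpha: float = 0.05,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Attach specificity categories to significant scan records.

    Genes absent from the nTPM matrix are categorized 'unannotated' and
    excluded from the cell-specific denominator.  Summary counts are at
    the gene level over the union of both hit lists:

    - ``n_hit_genes``: unique significant genes
    - ``n_cell_specific``: hit genes with category != none (annotated only)
    - ``n_oligo_lineage``: hit genes whose call involves the oligo lineage
      (a 'single' call on an oligo-lineage type, or 'oligoMultiCell')
    - ``n_unannotated``: hit genes missing from the nTPM matrix
    """
    annotated = records.copy()
    known = set(calls.index)
    cats = []
    for gene in annotated["gene_symbol"]:
        cats.append(calls.loc[gene, "category"] if gene in known else "unannotated")
    annotated["category"] = cats

    sig = annotated[(annotated["p_value"].notna()) & (annotated["p_value"] < alpha)]
    hit_genes = sig["gene_symbol"].unique()
    n_specific = 0
    n_oligo = 0
    n_unannotated = 0
    for gene in hit_genes:
        if gene not in known:
            n_unannotated += 1
            continue
        category = calls.loc[gene, "category"]
        if category == "none":
            continue
        n_specific += 1
        enriched = set(filter(None, str(calls.loc[gene, "enriched_types"]).split(";")))
        if category == "oligoMultiCell" or (
            category == "single" and enriched & vocab.oligo_lineage
        ):
            n_oligo += 1
    summary = {
        "n_hit_genes": int(len(hit_genes)),
        "n_cell_specific": n_specific,
        "n_oligo_lineage": n_oligo,
        "n_unannotated": n_unannotated,
    }
    return annotated, summary
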