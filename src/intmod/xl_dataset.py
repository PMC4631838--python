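"""Cross-link spectral match (CSM) filtering, target-decoy FDR estimation,
dataset merging, module classification, and validation against known
structures.

A CSM is one MS2 spectrum assigned to a cross-linked peptide pair.  Unique
residue pairs ("cross-links") are the unordered pairs of (protein, residue)
endpoints; identical pairs from different spectra or datasets merge with
spectral counts summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CrossLink",
    "CrossLinkSet",
    "FilterParams",
    "filter_csms",
    "estimate_fdr",
    "merge_crosslink_sets",
    "classify_crosslinks",
    "map_crosslinks_to_structure",
    "csms_to_crosslinks",
]

INTRA = "intra_module"
INTER = "inter_module"


def pair_key(protein1, residue1, protein2, residue2):
    """Canonical unordered-pair identity of a cross-link."""
    a = (str(protein1), int(residue1))
    b = (str(protein2), int(residue2))
    return (a, b) if a <= b else (b, a)


@dataclass
class CrossLink:
    protein1: str
    residue1: int
    protein2: str
    residue2: int
    n_spectra: int = 1
    source: str = ""
    xl_class: str | None = None  # intra_module | inter_module, assigned later
    meta: dict = field(default_factory=dict)  # e.g. hidden truth labels

    def __post_init__(self):
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be >= 1")
        (p1, r1), (p2, r2) = pair_key(self.protein1, self.residue1, self.protein2, self.residue2)
        self.protein1, self.residue1, self.protein2, self.residue2 = p1, r1, p2, r2

    @property
    def key(self):
        return pair_key(self.protein1, self.residue1, self.protein2, self.residue2)


class CrossLinkSet:
    """A set of unique residue-pair restraints with provenance metadata."""

    def __init__(self, links=None, provenance: str = ""):
        self._links: dict = {}
        self.provenance = provenance
        for xl in links or []:
            self._add(xl)

    @classmethod
    def from_links(cls, links, provenance: str = ""):
        return cls(links=links, provenance=provenance)

    def _add(self, xl: CrossLink) -> None:
        key = xl.key
        if key in self._links:
            old = self._links[key]
            sources = sorted(set(filter(None, old.source.split("+") + xl.source.split("+"))))
            merged = replace(
                old,
                n_spectra=old.n_spectra + xl.n_spectra,
                source="+".join(sources),
                meta={**old.meta, **xl.meta},
            )
            self._links[key] = merged
        else:
            self._links[key] = replace(xl)

    def __len__(self) -> int:
        return len(self._links)

    def __iter__(self):
        return iter(self._links.values())

    def __contains__(self, key) -> bool:
        return key in self._links

    @property
    def links(self):
        return list(self._links.values())

    def total_spectra(self) -> int:
        return sum(xl.n_spectra for xl in self)

    def subset(self, predicate):
        return CrossLinkSet(
            [xl for xl in self if predicate(xl)], provenance=self.provenance
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "protein1": xl.protein1,
                    "residue1": xl.residue1,
                    "protein2": xl.protein2,
                    "residue2": xl.residue2,
                    "n_spectra": xl.n_spectra,
                    "source": xl.source,
                    "xl_class": xl.xl_class,
                }
                for xl in self
            ]
        )


# ---------------------------------------------------------------------------
# CSM filtering
# ---------------------------------------------------------------------------

CSM_SCORE_COLUMNS = [
    "peptide_score",
    "expect_peptide",
    "expect_protein",
    "expect_worse",
    "score_difference",
    "classifier_score",
]


@dataclass
class FilterParams:
    """Spectral-match quality filters.

    A CSM is discarded when its peptide score is below ``min_peptide_score``,
    any of the three expectation values exceeds ``max_expectation``, its
    score difference is negative, or either peptide is shorter than
    ``min_peptide_length`` residues.  When one spectrum has several candidate
    peptide-pair interpretations, the top classifier-score match is kept only
    if the runner-up is more than ``ambiguity_gap`` decision-value units
    lower; ties resolve in favor of intra-protein interpretations.
    """

    min_peptide_score: float = 20.0
    max_expectation: float = 50.0
    min_score_difference: float = 0.0
    min_peptide_length: int = 4
    ambiguity_gap: float = 0.3


def filter_csms(csms: pd.DataFrame, params: FilterParams | None = None) -> pd.DataFrame:
    """Apply CSM quality filters and spectrum-level disambiguation.

    Returns the retained CSMs with two added boolean columns:
    ``ambiguous`` (spectrum has competing interpretations within the
    decision-value gap) and ``is_decoy`` (either peptide maps to a decoy
    protein; decoys are retained here and removed only at reporting stage).
    """
    params = params or FilterParams()
    for col in CSM_SCORE_COLUMNS:
        if col not in csms.columns:
            raise ValueError(f"CSM table missing score column {col!r}")
    df = csms.copy()
    keep = (
        (df["peptide_score"] >= params.min_peptide_score)
        & (df["expect_peptide"] <= params.max_expectation)
        & (df["expect_protein"] <= params.max_expectation)
        & (df["expect_worse"] <= params.max_expectation)
        & (df["score_difference"] >= params.min_score_difference)
    )
    if "peptide1_length" in df.columns:
        keep &= df["peptide1_length"] >= params.min_peptide_length
    if "peptide2_length" in df.columns:
        keep &= df["peptide2_length"] >= params.min_peptide_length
    df = df[keep].copy()

    is_decoy = np.zeros(len(df), dtype=bool)
    if "is_decoy1" in df.columns:
        is_decoy |= df["is_decoy1"].astype(bool).to_numpy()
    if "is_decoy2" in df.columns:
        is_decoy |= df["is_decoy2"].astype(bool).to_numpy()
    df["is_decoy"] = is_decoy
    df["ambiguous"] = False

    if "spectrum_id" not in df.columns:
        return df.reset_index(drop=True)

    # spectrum-level disambiguation between competing peptide-pair matches
    kept_rows = []
    for _, group in df.groupby("spectrum_id", sort=False):
        if len(group) == 1:
            kept_rows.append(group)
            continue
        order = group.sort_values("classifier_score", ascending=False, kind="mergesort")
        top, runner = order.iloc[0], order.iloc[1]
        gap = top["classifier_score"] - runner["classifier_score"]
        if gap > params.ambiguity_gap:
            kept_rows.append(order.iloc[[0]])
        elif gap == 0.0 and "protein1" in group.columns:
            # exact tie: prefer the intra-protein interpretation
            intra = order[order["protein1"] == order["protein2"]]
            chosen = intra.iloc[[0]] if len(intra) else order.iloc[[0]]
            chosen = chosen.assign(ambiguous=True)
            kept_rows.append(chosen)
        else:
            amb = order.iloc[[0, 1]].assign(ambiguous=True)
            kept_rows.append(amb)
    out = pd.concat(kept_rows, axis=0)
    return out.sort_index(kind="mergesort").reset_index(drop=True)


def estimate_fdr(csms: pd.DataFrame, threshold: float, decoy_ratio: float = 10.0) -> float:
    """Target-decoy FDR at a classifier-score threshold.

    FDR = (decoy hits at threshold / decoy_ratio) / target hits, where
    ``decoy_ratio`` accounts for a decoy database ``decoy_ratio`` times the
    size of the target database.  Returns 0.0 when there are no decoy hits.
    """
    if decoy_ratio <= 0:
        raise ValueError("decoy_ratio must be positive")
    hits = csms[csms["classifier_score"] >= threshold]
    if "is_decoy" in hits.columns:
        decoy = hits["is_decoy"].astype(bool)
    else:
        decoy = hits["is_decoy1"].astype(bool) | hits["is_decoy2"].astype(bool)
    n_decoy = int(decoy.sum())
    n_target = int((~decoy).sum())
    if n_target == 0:
        raise ZeroDivisionError("no target hits at this threshold; FDR undefined")
    if n_decoy == 0:
        return 0.0
    return (n_decoy / decoy_ratio) / n_target


def csms_to_crosslinks(
    csms: pd.DataFrame, source: str = "", drop_decoys: bool = True
) -> CrossLinkSet:
    """Collapse retained CSMs to unique residue-pair cross-links.

    Decoy matches are removed at this reporting stage.  Site-ambiguous CSMs
    (``site_weight`` column below 1) contribute their spectral count divided
    equally over candidate residue pairs.
    """
    df = csms
    if drop_decoys and "is_decoy" in df.columns:
        df = df[~df["is_decoy"].astype(bool)]
    counts: dict = {}
    for _, row in df.iterrows():
        key = pair_key(row["protein1"], row["residue1"], row["protein2"], row["residue2"])
        counts[key] = counts.get(key, 0.0) + float(row.get("site_weight", 1.0))
    links = [
        CrossLink(
            protein1=a[0],
            residue1=a[1],
            protein2=b[0],
            residue2=b[1],
            n_spectra=max(1, int(round(n))),
            source=source,
        )
        for (a, b), n in counts.items()
    ]
    return CrossLinkSet.from_links(links, provenance=source)


def merge_crosslink_sets(a: CrossLinkSet, b: CrossLinkSet) -> CrossLinkSet:
    """Union of two cross-link sets under unordered-pair identity.

    Shared pairs appear once, with spectral counts summed and both source
    labels retained.  The merge is commutative and associative.
    """
    merged = CrossLinkSet(provenance="+".join(filter(None, [a.provenance, b.provenance])))
    for xl in list(a) + list(b):
        merged._add(xl)
    return merged


def classify_crosslinks(xlset: CrossLinkSet, topology) -> CrossLinkSet:
    """Label each link intra_module or inter_module under the topology's
    per-residue-range module assignment."""
    out = []
    for xl in xlset:
        m1 = topology.module_of(xl.protein1, xl.residue1)
        m2 = topology.module_of(xl.protein2, xl.residue2)
        out.append(replace(xl, xl_class=INTRA if m1 == m2 else INTER))
    return CrossLinkSet.from_links(out, provenance=xlset.provenance)


def map_crosslinks_to_structure(
    xlset: CrossLinkSet,
    model,
    threshold: float = 35.0,
    chain_of: dict | None = None,
):
    """Map links onto an :class:`~intmod.io_formats.AtomicModel` and flag
    violations of the Cα–Cα distance threshold (default 35 Å).

    Links with an endpoint absent from the model are reported unmappable and
    excluded from the violation denominator.  Returns a per-link DataFrame
    and a summary dict.
    """
    chain_of = chain_of or {}
    rows = []
    for xl in xlset:
        rec = {
            "protein1": xl.protein1,
            "residue1": xl.residue1,
            "protein2": xl.protein2,
            "residue2": xl.residue2,
            "mappable": False,
            "distance": np.nan,
            "violated": False,
        }
        try:
            c1 = chain_of.get(xl.protein1, xl.protein1)
            c2 = chain_of.get(xl.protein2, xl.protein2)
            r1 = model.residue(c1, xl.residue1)
            r2 = model.residue(c2, xl.residue2)
        except KeyError:
            rows.append(rec)
            continue
        d = float(np.linalg.norm(r1.ca - r2.ca))
        rec.update(mappable=True, distance=d, violated=d > threshold)
        rows.append(rec)
    df = pd.DataFrame(rows)
    mappable = df[df["mappable"]]
    hist_edges = np.arange(0.0, 105.0, 5.0)
    hist, _ = np.histogram(mappable["distance"].dropna(), bins=hist_edges)
    summary = {
        "n_links": len(df),
        "n_mappable": int(df["mappable"].sum()),
        "n_violated": int(mappable["violated"].sum()),
        "violated_fraction": (
            float(mappable["violated"].mean()) if len(mappable) else np.nan
        ),
        "threshold": threshold,
        "distance_histogram": {"edges": hist_edges.tolist(), "counts": hist.tolist()},
    }
    return df, summary
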