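"""Mapping discovered SDOH categories onto a reference taxonomy.

Each discovered category row (category, up to three subcategories, and a
free-text definition) is concatenated into a single string, embedded with
the same encoder as the reference measure names, and compared by cosine
similarity. A pair is declared a match when its similarity is *strictly
greater* than the upper hinge of the full similarity distribution,

    upper hinge = Q3 + 1.5 × IQR,

the boxplot upper fence (about three standard deviations above the mean
under normality). Coverage is the percentage of discovered categories with
at least one match; one category may legitimately map to several reference
measures.

A 36-row SDOH category table is bundled as ``data/sdoh_categories.csv``;
the reference side (e.g. PhenX SDOH protocol names) is user-supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .embedding import Encoder, encode_texts, pairwise_similarity

TAXONOMY_COLUMNS = ("Category", "Subcategory 1", "Subcategory 2", "Subcategory 3", "Definition")


@dataclass(frozen=True)
class TaxonomyEntry:
    category: str
    subcategory1: str | None = None
    subcategory2: str | None = None
    subcategory3: str | None = None
    definition: str = ""

    def __post_init__(self) -> None:
        if not self.category or not self.definition:
            raise ValueError("category and definition must be non-empty")
        subs = (self.subcategory1, self.subcategory2, self.subcategory3)
        seen_gap = False
        for s in subs:
            if not s:
                seen_gap = True
            elif seen_gap:
                raise ValueError("subcategories must fill left-to-right")

    @property
    def key(self) -> str:
        """Category plus subcategory path; keeps same-top-level rows distinct."""
        parts = [self.category, self.subcategory1, self.subcategory2, self.subcategory3]
        return "/".join(p for p in parts if p)


@dataclass
class MappingResult:
    edges: list[tuple[str, str, float]]  # (category_key, reference_name, similarity)
    threshold: float
    coverage_percent: float
    unmapped: list[str]
    similarities: np.ndarray  # full pairwise matrix (histogram source)
    category_keys: list[str]
    reference_names: list[str]


def bundled_category_table() -> list[TaxonomyEntry]:
    """The bundled SDOH category table (36 rows)."""
    with resources.files("semharm.data").joinpath("sdoh_categories.csv").open("r") as fh:
        return load_taxonomy(fh)


def load_taxonomy(source) -> list[TaxonomyEntry]:
    """Read a taxonomy CSV with columns Category, Subcategory 1–3, Definition."""
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"taxonomy file is missing column {missing[0]!r}")
    entries = []
    for row in df.to_dict(orient="records"):
        entries.append(
            TaxonomyEntry(
                category=row["Category"],
                subcategory1=row["Subcategory 1"] or None,
                subcategory2=row["Subcategory 2"] or None,
                subcategory3=row["Subcategory 3"] or None,
                definition=row["Definition"],
            )
        )
    return entries


def build_category_strings(entries: Sequence[TaxonomyEntry]) -> list[str]:
    """Join category, subcategories and definition with ", ", skipping blanks."""
    out = []
    for e in entries:
        parts = [e.category, e.subcategory1, e.subcategory2, e.subcategory3, e.definition]
        out.append(", ".join(p for p in parts if p))
    return out


def upper_hinge_threshold(values: Sequence[float]) -> float:
    """Boxplot upper fence Q3 + 1.5·IQR with linear-interpolation quantiles."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("upper hinge of an empty list is undefined")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return float(q3 + 1.5 * (q3 - q1))


def map_categories(
    category_strings: Sequence[str],
    reference_names: Sequence[str],
    encoder: Encoder,
    category_keys: Sequence[str] | None = None,
    threshold: float | None = None,
) -> MappingResult:
    """Threshold pairwise category↔reference cosine similarities.

    The threshold defaults to the upper hinge over *all* pairwise
    similarities; edges are the strictly-greater-than-threshold pairs.
    ``threshold`` may be injected for sensitivity analyses.
    """
    if len(category_strings) == 0 or len(reference_names) == 0:
        raise ValueError("both category and reference lists must be non-empty")
    if category_keys is None:
        category_keys = list(category_strings)
    if len(category_keys) != len(category_strings):
        raise ValueError("category_keys must align with category_strings")
    cats = encode_texts(category_strings, encoder)
    refs = encode_texts(reference_names, encoder)
    sims = pairwise_similarity(cats, refs)
    return threshold_mapping(sims, list(category_keys), list(reference_names), threshold)


def threshold_mapping(
    sims: np.ndarray,
    category_keys: list[str],
    reference_names: list[str],
    threshold: float | None = None,
) -> MappingResult:
    """Apply the upper-hinge edge rule to a precomputed similarity matrix."""
    sims = np.asarray(sims, dtype=float)
    if sims.shape != (len(category_keys), len(reference_names)):
        raise ValueError("similarity matrix shape does not match the key lists")
    if threshold is None:
        threshold = upper_hinge_threshold(sims.ravel())
    edges = [
        (category_keys[i], reference_names[j], float(sims[i, j]))
        for i, j in zip(*np.nonzero(sims > threshold))
    ]
    mapped = {e[0] for e in edges}
    unmapped = [k for k in category_keys if k not in mapped]
    coverage = 100.0 * (len(category_keys) - len(unmapped)) / len(category_keys)
    return MappingResult(
        edges=edges,
        threshold=float(threshold),
        coverage_percent=coverage,
        unmapped=unmapped,
        similarities=sims,
        category_keys=list(category_keys),
        reference_names=list(reference_names),
    )


def write_mapping(result: MappingResult, out_dir: str | Path) -> dict[str, str]:
    """Persist edges CSV, histogram data CSV and a JSON report; returns paths."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges_path = out / "mapping_edges.csv"
    pd.DataFrame(result.edges, columns=["category_key", "reference_name", "similarity"]).to_csv(
        edges_path, index=False
    )
    hist_path = out / "similarity_histogram.csv"
    pd.DataFrame({"similarity": result.similarities.ravel()}).to_csv(hist_path, index=False)
    report_path = out / "mapping_report.json"
    report_path.write_text(
        json.dumps(
            {
                "threshold": result.threshold,
                "coverage_percent": result.coverage_percent,
                "n_categories": len(result.category_keys),
                "n_references": len(result.reference_names),
                "n_edges": len(result.edges),
                "unmapped": result.unmapped,
            },
            indent=1,
        )
    )
    return {"edges": str(edges_path), "histogram": str(hist_path), "report": str(report_path)}
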