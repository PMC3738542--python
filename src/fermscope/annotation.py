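"""Functional-category tallies for differentially expressed gene sets.

Works against a user-supplied gene -> term map (e.g. GO or a GenProtEC-style
classification exported as a two-column TSV); the package never downloads
or parses ontology releases itself.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .errors import DesignError

UNANNOTATED = "unannotated"


def read_annotation_map(path) -> pd.DataFrame:
    """Two-column TSV (gene, term) -> long annotation frame."""
    frame = pd.read_csv(path, sep="\t", header=0)
    if frame.shape[1] < 2:
        raise DesignError("annotation map needs two columns: gene, term")
    frame.columns = ["gene", "term", *frame.columns[2:]]
    return frame[["gene", "term"]]


def category_tally(
    genes: Iterable[str],
    annotation: pd.DataFrame | Mapping[str, set],
    k: int | None = None,
) -> pd.DataFrame:
    """Top-``k`` term counts over a gene set.

    A term's count is the number of set genes annotated with it; a gene may
    contribute to many terms.  Genes lacking any annotation are tallied
    under ``unannotated``.  Ties are broken by term id (lexicographic), and
    ``k=None`` returns every term.  Returns a frame with columns term,
    count.
    """
    gene_set = set(genes)
    if not gene_set:
        return pd.DataFrame(columns=["term", "count"])
    if isinstance(annotation, Mapping):
        long = pd.DataFrame(
            [(g, t) for g, terms in annotation.items() for t in terms],
            columns=["gene", "term"],
        )
    else:
        long = annotation[["gene", "term"]]
    hits = long[long["gene"].isin(gene_set)]
    counts = hits.groupby("term")["gene"].nunique()
    n_unannotated = len(gene_set - set(hits["gene"]))
    if n_unannotated:
        counts = pd.concat([counts, pd.Series({UNANNOTATED: n_unannotated})])
    table = (
        counts.rename("count")
        .reset_index()
        .rename(columns={"index": "term"})
        .sort_values(["count", "term"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return table.head(k) if k is not None else table
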