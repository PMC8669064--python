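"""End-to-end stage wiring shared by the CLI, tests, and scripts."""

from __future__ import annotations

from typing import Sequence

from .genome import GenomicInterval
from .matrix import (
    ContactMatrix,
    OEMatrix,
    balance_ice,
    observed_expected,
    stitch_interchromosomal,
)
from .subcompartments import (
    ClusterParams,
    LabelTrack,
    assign_names,
    cluster_loci,
    filter_and_merge,
)

__all__ = ["balanced_oe", "call_subcompartments"]


def balanced_oe(
    contacts: ContactMatrix,
    mode: str = "both",
    tol: float = 1e-8,
    max_iter: int = 500,
) -> OEMatrix:
    """Balance a contact matrix and transform it to observed/expected."""
    bal = balance_ice(contacts, tol=tol, max_iter=max_iter)
    if not bal.converged:
        raise RuntimeError(
            f"matrix balancing did not converge in {bal.n_iter} iterations"
        )
    return observed_expected(bal.balanced, bal.mask, contacts.layout, mode=mode)


def call_subcompartments(
    contacts: ContactMatrix,
    lads: Sequence[GenomicInterval],
    params: ClusterParams = ClusterParams(),
    odd_set: Sequence[str] | None = None,
    even_set: Sequence[str] | None = None,
    provenance: str = "",
) -> LabelTrack:
    """The full subcompartment-calling procedure.

    Balance, transform to trans observed/expected, stitch odd-by-even,
    k-means both axes, discard sub-5% clusters, merge the survivors by
    genomic-size rank, and name the merged clusters A/B by LAD
    concordance with numbering by decreasing size.
    """
    oe = balanced_oe(contacts, mode="trans_pair_mean")
    stitched = stitch_interchromosomal(oe, odd_set, even_set)
    row_clusters, col_clusters = cluster_loci(stitched, params)
    merged, _ = filter_and_merge(row_clusters, col_clusters, stitched, params)
    return assign_names(merged, lads, contacts.layout, provenance=provenance)
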