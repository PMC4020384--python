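import numpy as np
import pytest

from chronoseq import HKY, Partition, SiteRateModel, parse_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def three_taxon_tree():
    """The fixed validation topology used throughout the suite."""
    return parse_tree("((A:0.3,B:0.3):0.2,C:0.5);")


@pytest.fixture
def hky4_gamma_partition(three_taxon_tree):
    """HKY kappa=4 with 4 gamma categories (shape 0.5) on the 3-taxon tree."""

    def make(n_sites: int) -> Partition:
        return Partition(
            n_sites=n_sites,
            tree=three_taxon_tree,
            subst=HKY(kappa=4.0),
            site_model=SiteRateModel(alpha=0.5, n_categories=4),
        )

    return make


def pattern_counts(alignment, patterns, chunk=1):
    """Tally pattern occurrences column-wise over an alignment."""
    counts = {p: 0 for p in patterns}
    rows = [alignment.rows[n] for n in alignment.taxa]
    for col in range(0, alignment.n_columns, chunk):
        pat = tuple(r[col : col + chunk] for r in rows)
        counts[pat] += 1
    return counts
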