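import numpy as np
import pytest

from metmap import DEFAULT_PARAMS, CGSite
from metmap.model import SitePosterior, PosteriorTable


@pytest.fixture
def params():
    return DEFAULT_PARAMS


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_posterior_table(records, params=DEFAULT_PARAMS):
    """Assemble a PosteriorTable from (chrom, pos, is_hpaii, p_island[, score])
    tuples for tests that exercise downstream consumers directly."""
    out = []
    for rec in records:
        chrom, pos, is_hpaii, p_island = rec[:4]
        site = CGSite(chrom, pos, is_hpaii)
        if is_hpaii:
            score = rec[4]
            # encode the requested score as pure U mass
            out.append(
                SitePosterior(
                    site, p_island=p_island, p_u=score, p_p=0.0, p_m=1.0 - score
                )
            )
        else:
            out.append(SitePosterior(site, p_island=p_island))
    return PosteriorTable(out, params)
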