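import numpy as np
import pytest

from genematch.universe import GeneRecord, GeneSet, GeneUniverse


def make_universe(records):
    """Build a universe from (symbol, log_expr, cds, tx, clip) tuples; None allowed."""
    return GeneUniverse(
        [
            GeneRecord(
                symbol=sym,
                log_expr=expr,
                cds_len_log2=cds,
                tx_len_log2=tx,
                clip_count=clip,
            )
            for sym, expr, cds, tx, clip in records
        ]
    )


@pytest.fixture
def tiny_universe():
    return make_universe(
        [
            ("A1", 1.9, 9.0, 10.0, 0),
            ("B2", 2.0, 8.0, 11.0, 3),
            ("C3", 2.1, None, 12.0, 7),
            ("D4", 5.0, 10.0, 12.5, 120),
            ("E5", 7.5, 11.0, 13.0, 900),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def gaussian_universe(n, seed, mean=0.0, sd=1.0):
    """Universe whose log_expr is N(mean, sd^2); lengths present and boring."""
    r = np.random.default_rng(seed)
    expr = r.normal(mean, sd, size=n)
    return GeneUniverse(
        [
            GeneRecord(symbol=f"S{i:05d}", log_expr=float(expr[i]), cds_len_log2=10.0 + 1e-3 * i, tx_len_log2=11.0 + 1e-3 * i)
            for i in range(n)
        ]
    )


def gene_set(name, *symbols):
    return GeneSet.from_symbols(name, symbols)
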