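"""Bundled reference fixtures: transcribed worked-example tables.

``table1`` carries the representative-SNP rows of the 32 known imprinted
transcripts confirmed in the MEF reciprocal-cross experiment; ``table2`` the
eight imprinted transcript extensions.  Count quadruples marked
``counts_reconstructed=yes`` could not be recovered digit-exactly from the
source table text and were reconstructed to reproduce the printed AF columns
at two-decimal half-up rounding; the printed AF and FDR columns themselves
are stored verbatim.  The known-imprinted-transcript catalogue fixture is a
synthetic stand-in: the 32 confirmed gene names are real, the remaining rows
are placeholders that reproduce the published category tallies (22 small
RNAs, 12 not genuine, 1 duplicate, 61 low-expression no-calls, 5 SNP-less
no-calls, 19 not confirmed including the leaky Dlk1).
"""

from importlib import resources

import pandas as pd

_PKG = "imprintcall.data"


def _read(name: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table1() -> pd.DataFrame:
    """Representative-SNP rows of the 32 confirmed known imprinted transcripts."""
    return _read("table1_known_imprinted.tsv")


def load_table2() -> pd.DataFrame:
    """The eight imprinted transcript extensions with spans and SNP support."""
    return _read("table2_extensions.tsv")


def load_catalogue() -> pd.DataFrame:
    """Synthetic stand-in for the 152-transcript known-imprinted catalogue."""
    return _read("known_imprinted_catalogue_synthetic.tsv")
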