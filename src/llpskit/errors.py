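"""Exception types shared across the package."""


class FormatError(ValueError):
    """Malformed input file (FASTA/alignment/table/prediction dialect)."""


class CatalogError(ValueError):
    """Invalid motif catalog entry (raised at load time, never at scan time)."""
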