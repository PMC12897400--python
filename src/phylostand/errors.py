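"""Exception hierarchy shared across the pipeline."""


class PhylostandError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(PhylostandError):
    """Input data violates a documented invariant (bad tree, bad plot, bad config)."""


class NewickParseError(ValidationError):
    """Newick text could not be parsed; carries position information when known."""


class NumericalError(PhylostandError):
    """A fit or statistic could not be computed (singular design, degenerate null)."""
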