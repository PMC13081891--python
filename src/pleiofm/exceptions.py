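"""Exception hierarchy shared across the package."""


class PleiofmError(Exception):
    """Base class for package errors."""


class ParameterError(PleiofmError, ValueError):
    """Invalid or out-of-range configuration / model parameters."""


class DataError(PleiofmError, ValueError):
    """Input data violate a model precondition (non-finite, wrong support, ...)."""


class FormatError(PleiofmError, ValueError):
    """A delimited input file does not follow the expected dialect."""


class InsufficientDataError(DataError):
    """Too few observations to fit the requested model."""


class MissingSNPError(PleiofmError, KeyError):
    """A weight refers to a SNP absent from the genotype matrix."""

    def __init__(self, gene_id, snp_id):
        self.gene_id = gene_id
        self.snp_id = snp_id
        super().__init__(f"gene {gene_id!r}: SNP {snp_id!r} not found in genotype matrix")


class NumericError(PleiofmError, FloatingPointError):
    """A sampler produced a non-finite draw; message names the update block."""
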