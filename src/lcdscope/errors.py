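"""Exception hierarchy shared across lcdscope modules."""


class LcdscopeError(Exception):
    """Base class for all lcdscope errors."""


class ConfigurationError(LcdscopeError, ValueError):
    """Invalid search/run configuration (e.g. incompatible thresholds)."""


class FormatError(LcdscopeError, ValueError):
    """Malformed input file (FASTA/OBO/GAF/TSV)."""


class ConsistencyError(LcdscopeError, ValueError):
    """Cross-referenced objects disagree (unknown accession, key mismatch)."""


class SchemaError(LcdscopeError, ValueError):
    """Tabular row does not satisfy the declared column schema."""
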