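"""Exception hierarchy shared across the package.

Two broad failure classes are distinguished because the command line maps
them to different exit codes: configuration problems (bad enzyme
definitions, malformed primer files, out-of-range settings) and data
problems (illegal residues, unlabelled alignment rows, templates that
amplify more than once).
"""


class RflpError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RflpError):
    """A configuration file or setting is invalid."""


class DataError(RflpError):
    """An input sequence, alignment or band list is invalid."""


class FixtureError(RflpError):
    """The synthetic-template generator could not satisfy its constraints."""
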