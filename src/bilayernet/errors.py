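"""Exception hierarchy shared across the package."""


class BilayerNetError(Exception):
    """Base class for all package-specific errors."""


class InputError(BilayerNetError):
    """Fatal problem with an input file or an empty/inconsistent input."""


class ConfigError(BilayerNetError):
    """Invalid run configuration; carries the full list of problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
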