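"""Exception hierarchy shared by all modules.

Each error class carries the process exit code the command-line layer maps
it to: 2 for invalid input, 3 for an exceeded enumeration cap, 4 for an
internal consistency failure (conditions the theory proves impossible on
valid inputs, kept as hard checks).
"""


class UrefineError(Exception):
    exit_code = 1


class InvalidInputError(UrefineError):
    exit_code = 2


class CapExceededError(UrefineError):
    exit_code = 3


class InternalConsistencyError(UrefineError):
    exit_code = 4
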