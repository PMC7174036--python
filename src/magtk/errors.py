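"""Exception hierarchy shared across the toolkit.

``InputError`` marks problems a user can fix (bad files, bad flags) and maps
to exit code 1 in the CLI; anything else is an internal error (exit code 2).
"""


class ToolkitError(Exception):
    """Base class for all magtk errors."""


class InputError(ToolkitError):
    """Malformed or inconsistent user input (files, tables, parameters)."""


class FormatError(InputError):
    """A file does not follow its declared dialect."""


class StateError(ToolkitError):
    """An operation was applied to an object in the wrong state."""
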