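"""Exception hierarchy for sdmkit."""


class SdmKitError(Exception):
    """Base class for all sdmkit errors."""


class SlugError(SdmKitError, ValueError):
    """An identifier does not conform to the slug grammar."""


class MeasureCollisionError(SdmKitError, ValueError):
    """Two measures with the same id were added to one measure set."""


class FlagReferenceError(SdmKitError, KeyError):
    """A flag target does not resolve within its reading."""


class InsufficientDataError(SdmKitError, ValueError):
    """A signal or log is too short for the requested computation."""


class ValidationError(SdmKitError, ValueError):
    """A document violates the canonical reading schema.

    ``pointer`` holds the JSON-pointer path of the offending element.
    """

    def __init__(self, message: str, pointer: str = ""):
        super().__init__(f"{pointer}: {message}" if pointer else message)
        self.pointer = pointer
        self.message = message


class ConfigurationError(SdmKitError, ValueError):
    """A pipeline or registry declaration is inconsistent (e.g. cyclic)."""


class UnknownTestError(SdmKitError, KeyError):
    """An evaluation code is not present in the test registry."""
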