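"""Exception hierarchy.

Every error raised on a user-facing code path derives from
:class:`BrainsceneError` so callers (and the CLI) can catch one base class.
"""


class BrainsceneError(Exception):
    """Base class for all brainscene errors."""


class AtlasLoadError(BrainsceneError):
    """An atlas bundle is missing a required file or a file is unreadable."""


class AtlasValidationError(BrainsceneError):
    """The atlas content violates a structural invariant (duplicate ids,
    hierarchy cycle, orphan annotation label, non-positive resolution)."""


class StructureLookupError(BrainsceneError, KeyError):
    """An acronym or id does not resolve to a structure.

    Carries ``suggestions``: the nearest known acronyms, for error messages.
    """

    def __init__(self, message: str, suggestions: tuple = ()):
        super().__init__(message)
        self.suggestions = tuple(suggestions)

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class FormatError(BrainsceneError, ValueError):
    """A data file does not conform to its format (SWC/OBJ/STL/NPY/CSV/JSON/TIFF)."""


class EmptyRegionError(BrainsceneError):
    """A region has no labeled voxels (and no stored mesh) to build geometry from."""


class EmptyMeshError(BrainsceneError):
    """An operation that needs geometry received a mesh with no faces."""


class FixtureGenerationError(BrainsceneError):
    """A synthetic dataset could not be generated under the requested
    parameters (e.g. regions cannot be placed without overlap)."""


class SceneConfigError(BrainsceneError):
    """A scene configuration file is invalid; ``problems`` lists every issue found."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid scene config:\n" + "\n".join(f"  - {p}" for p in self.problems))
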