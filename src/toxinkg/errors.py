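"""Exception hierarchy for toxinkg."""


class ToxinKGError(Exception):
    """Base class for all package errors."""


class PathResolutionError(ToxinKGError):
    """A slash-delimited field path does not resolve against a guideline profile.

    Carries the failing segment and the candidate sibling names at that level.
    """

    def __init__(self, path: str, segment: str, candidates: list[str]):
        self.path = path
        self.segment = segment
        self.candidates = sorted(candidates)
        msg = f"cannot resolve segment {segment!r} in path {path!r}"
        if self.candidates:
            msg += f"; known names at this level: {', '.join(self.candidates)}"
        super().__init__(msg)


class ProfileError(ToxinKGError):
    """A guideline profile definition violates its structural invariants."""


class IngestError(ToxinKGError):
    """Fatal problem reading a curated CSV file (unreadable, missing id columns)."""


class NotScorableError(ToxinKGError):
    """Reliability scoring requested for a study outside the scorer's scope
    (non-OECD studies carry free text only and are excluded from automation)."""


class ContractError(ToxinKGError):
    """An operation was called with a value outside its stated domain."""


class SmilesParseError(ToxinKGError):
    """Input string is not a parseable SMILES."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class UnsupportedStructureError(ToxinKGError):
    """Structure cannot be given a canonical SMILES (e.g. polymer ingredients)."""


class UndefinedSimilarityError(ToxinKGError):
    """Dice similarity is undefined when both feature sets are empty."""


class UndefinedMetricError(ToxinKGError):
    """A ratio metric was requested with a zero denominator."""


class MappingError(ToxinKGError):
    """A CSV-to-RDF mapping rule references a column absent from its source."""


class ConfigError(ToxinKGError):
    """Invalid generator or run configuration."""
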