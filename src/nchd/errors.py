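"""Exception hierarchy shared across the package."""


class NCHDError(Exception):
    """Base class for package errors."""


class SchemaError(NCHDError):
    """A tabular input does not match its declared schema."""


class GeometryError(NCHDError):
    """Invalid, overlapping, or geographically-projected geometry."""


class UnmappedCommunityError(NCHDError):
    """Community identifiers in a flow file missing from the lookup table."""

    def __init__(self, communities):
        self.communities = sorted(communities)
        super().__init__(
            "communities not present in the community-to-unit lookup: "
            + ", ".join(map(str, self.communities))
        )


class DegenerateScenarioError(NCHDError):
    """Input configuration that the procedure cannot meaningfully process."""
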