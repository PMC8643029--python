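"""Exception hierarchy for agreetree."""


class AgreeTreeError(Exception):
    """Base class for all agreetree errors."""


class NewickParseError(AgreeTreeError):
    """Malformed Newick input.

    Parameters
    ----------
    message:
        Human-readable description of the problem.
    offset:
        Character offset into the input at which the problem was detected.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class DuplicateLabelError(AgreeTreeError):
    """The same taxon labels two nodes of a single tree."""


class XTreeError(AgreeTreeError):
    """A structural X-tree invariant is violated (e.g. unlabeled unary node)."""


class ContractError(AgreeTreeError):
    """An operation was called outside its contract (internal consistency)."""
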