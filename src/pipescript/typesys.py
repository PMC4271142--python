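"""Type tags for the language's closed type system.

Scalars: bool, int, real, string.  Homogeneous lists are written ``T[]``.
There are no maps, objects or generics beyond lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class TypeTag:
    base: str  # bool | int | real | string | list | void | error
    element: Optional["TypeTag"] = None  # present iff base == 'list'

    def __post_init__(self):
        if self.base == "list" and self.element is None:
            raise ValueError("list type requires an element type")

    def __str__(self):
        if self.base == "list":
            return f"{self.element}[]"
        return self.base

    @property
    def is_list(self) -> bool:
        return self.base == "list"

    @property
    def is_numeric(self) -> bool:
        return self.base in ("int", "real")

    @property
    def is_scalar(self) -> bool:
        return self.base in ("bool", "int", "real", "string")


BOOL = TypeTag("bool")
INT = TypeTag("int")
REAL = TypeTag("real")
STRING = TypeTag("string")
VOID = TypeTag("void")
ERROR = TypeTag("error")  # sentinel to suppress cascaded diagnostics
STRING_LIST = TypeTag("list", STRING)


def list_of(element: TypeTag) -> TypeTag:
    return TypeTag("list", element)


def parse_tag(text: str) -> TypeTag:
    """Parse a printed tag like ``string[]`` back into a TypeTag."""
    depth = 0
    while text.endswith("[]"):
        text = text[:-2]
        depth += 1
    tag = TypeTag(text)
    for _ in range(depth):
        tag = list_of(tag)
    return tag


def assignable(target: TypeTag, value: TypeTag) -> bool:
    """Value may be stored in target: identical, or int widened to real."""
    if ERROR in (target, value):
        return True
    if target == value:
        return True
    if target == REAL and value == INT:
        return True
    return False


def default_value(tag: TypeTag):
    if tag.base == "bool":
        return False
    if tag.base == "int":
        return 0
    if tag.base == "real":
        return 0.0
    if tag.base == "string":
        return ""
    if tag.base == "list":
        return []
    raise ValueError(f"no default for {tag}")
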