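"""Provider plug-in registry: normalise foreign graph/tree objects.

Any object for which a registered provider's matcher returns True can be
rendered; the converter maps it onto the canonical :class:`~netcanvas.core.
NetworkData` / :class:`~netcanvas.core.TreeData`, after which all downstream
stages are provider-blind. Discovery is by registry precedence: providers
registered later (typically by users or third-party packages) are tried
before the built-ins, and the first matcher that fires wins, so detection is
deterministic without import probing.

Built-in providers:

``internal`` / ``internal_tree``
    Pass-through for the canonical containers themselves.
``edgelist``
    A mapping dialect with keys ``edges`` (required), ``vertices``,
    ``directed``, ``vertex_attrs``, ``edge_attrs``, and optionally ``layout``.
``newick``
    Strings in the toy Newick subset (nested parentheses, labels,
    ``:length``, terminating ``;``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

from .core import NetworkData, TreeData, build_network
from .errors import ConversionError, ProviderRegistrationError, UnsupportedInputError

__all__ = [
    "ProviderDescriptor",
    "ProviderRegistry",
    "register_provider",
    "detect_provider",
    "normalise",
    "default_registry",
]


@dataclass(frozen=True)
class ProviderDescriptor:
    """One input stream: how to recognise and convert a foreign object.

    ``matcher`` must be side-effect-free; ``converter`` returns NetworkData or
    TreeData; ``layout_extractor`` optionally pulls a raw vertex->coordinate
    mapping out of the object (e.g. a stored embedding).
    """

    name: str
    kind: str  # "network" | "tree"
    matcher: Callable[[object], bool]
    converter: Callable[[object], NetworkData | TreeData]
    layout_extractor: Callable[[object], Mapping] | None = None


class ProviderRegistry:
    def __init__(self, with_builtins: bool = True):
        self._builtins: list[ProviderDescriptor] = []
        self._user: list[ProviderDescriptor] = []
        if with_builtins:
            for descriptor in _make_builtins():
                self._builtins.append(descriptor)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self._ordered()]

    def _ordered(self) -> list[ProviderDescriptor]:
        # Later-registered user providers take precedence over earlier ones
        # and over every built-in.
        return list(reversed(self._user)) + self._builtins

    def register(self, descriptor: ProviderDescriptor) -> None:
        if descriptor.name in self.names:
            raise ProviderRegistrationError(
                f"provider {descriptor.name!r} is already registered"
            )
        if descriptor.kind not in ("network", "tree"):
            raise ProviderRegistrationError(
                f"provider kind must be 'network' or 'tree', got {descriptor.kind!r}"
            )
        self._user.append(descriptor)

    def unregister(self, name: str) -> None:
        self._user = [d for d in self._user if d.name != name]

    def detect(self, obj: object, kind: str | None = None) -> str:
        for descriptor in self._ordered():
            if kind is not None and descriptor.kind != kind:
                continue
            if descriptor.matcher(obj):
                return descriptor.name
        raise UnsupportedInputError(
            f"no registered provider accepts objects of type "
            f"{type(obj).__name__!r}; registered: {self.names}"
        )

    def normalise(
        self, obj: object, kind: str | None = None
    ) -> tuple[NetworkData | TreeData, Mapping | None]:
        """Detect and convert *obj*; also return any provider-supplied layout.

        The output depends only on the abstract graph (vertices, ordered
        edges, attributes), never on provider internals.
        """
        name = self.detect(obj, kind=kind)
        descriptor = next(d for d in self._ordered() if d.name == name)
        try:
            data = descriptor.converter(obj)
        except Exception as exc:  # noqa: BLE001 - wrapped with cause
            raise ConversionError(
                f"provider {name!r} failed to convert {type(obj).__name__}: {exc}"
            ) from exc
        layout = None
        if descriptor.layout_extractor is not None:
            layout = descriptor.layout_extractor(obj)
        return data, layout


def _edgelist_matches(obj: object) -> bool:
    return isinstance(obj, Mapping) and "edges" in obj


def _edgelist_convert(obj: Mapping) -> NetworkData:
    return build_network(
        edges=obj["edges"],
        vertex_ids=obj.get("vertices"),
        directed=obj.get("directed", False),
        vertex_attrs=obj.get("vertex_attrs"),
        edge_attrs=obj.get("edge_attrs"),
    )


def _edgelist_layout(obj: Mapping):
    return obj.get("layout")


def _newick_matches(obj: object) -> bool:
    return isinstance(obj, str) and obj.strip().endswith(";")


def _newick_convert(obj: str) -> TreeData:
    from .fixtures import parse_newick_toy

    return parse_newick_toy(obj)


def _make_builtins() -> list[ProviderDescriptor]:
    return [
        ProviderDescriptor(
            name="internal",
            kind="network",
            matcher=lambda obj: isinstance(obj, NetworkData),
            converter=lambda obj: obj,
        ),
        ProviderDescriptor(
            name="internal_tree",
            kind="tree",
            matcher=lambda obj: isinstance(obj, TreeData),
            converter=lambda obj: obj,
        ),
        ProviderDescriptor(
            name="edgelist",
            kind="network",
            matcher=_edgelist_matches,
            converter=_edgelist_convert,
            layout_extractor=_edgelist_layout,
        ),
        ProviderDescriptor(
            name="newick",
            kind="tree",
            matcher=_newick_matches,
            converter=_newick_convert,
        ),
    ]


#: Process-wide registry used by the high-level API.
default_registry = ProviderRegistry()


def register_provider(
    descriptor: ProviderDescriptor, registry: ProviderRegistry | None = None
) -> None:
    (registry or default_registry).register(descriptor)


def detect_provider(
    obj: object, kind: str | None = None, registry: ProviderRegistry | None = None
) -> str:
    return (registry or default_registry).detect(obj, kind=kind)


def normalise(
    obj: object, kind: str | None = None, registry: ProviderRegistry | None = None
) -> tuple[NetworkData | TreeData, Mapping | None]:
    return (registry or default_registry).normalise(obj, kind=kind)
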