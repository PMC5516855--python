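"""Multi-map bundles described by a CellDesigner configuration diagram.

A bundle is a set of map files uploaded together with one configuration
file — itself a CellDesigner diagram — whose elements name the member maps
(matched case-insensitively by file base name without extension) and whose
interactions denote relationships between the maps.

Link derivation:

* when the config diagram contains interactions, every (reactant-named map,
  product-named map) pair yields one link, with the config reactant element
  as the link's source element;
* when it contains none, every map-named element other than the main map
  yields one link main map → that map.

The main map is the first non-config file in input order.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from ..errors import BundleLinkError, UnsupportedDialect
from ..model import ElementType, MapModel, SubmapLink
from .celldesigner import read_celldesigner
from .sbgnml import read_sbgnml

#: link graph record: (source map_id, source element_id, target map_id)
LinkRecord = tuple[str, str, str]


@dataclass
class Bundle:
    maps: dict[str, MapModel] = field(default_factory=dict)
    main_map_id: str = ""
    link_graph: list[LinkRecord] = field(default_factory=list)

    @property
    def main_map(self) -> MapModel:
        return self.maps[self.main_map_id]


def _base_name(file_name: str) -> str:
    return Path(file_name).stem.casefold()


def _read_map(file_name: str, text: str) -> MapModel:
    if file_name.lower().endswith(".sbgn"):
        return read_sbgnml(text)
    return read_celldesigner(text)


def read_bundle(files: dict[str, str], config_name: str) -> Bundle:
    """Assemble a :class:`Bundle` from named XML texts.

    ``files`` maps file names to document texts; ``config_name`` names the
    configuration diagram among them.  Member maps are parsed per their
    extension (``.sbgn`` → SBGN-ML, anything else → CellDesigner).
    """
    if config_name not in files:
        raise BundleLinkError(config_name)
    config = read_celldesigner(files[config_name])

    bundle = Bundle()
    by_base: dict[str, str] = {}  # base name -> map_id
    for file_name, text in files.items():
        if file_name == config_name:
            continue
        map_model = _read_map(file_name, text)
        # map_id must be unique within the bundle; fall back to file base name
        map_id = map_model.map_id
        if not map_id or map_id in bundle.maps:
            map_id = Path(file_name).stem
            map_model.map_id = map_id
        bundle.maps[map_id] = map_model
        by_base[_base_name(file_name)] = map_id
        if not bundle.main_map_id:
            bundle.main_map_id = map_id
    if not bundle.maps:
        raise UnsupportedDialect("bundle contains no member maps")

    # config elements name member maps; non-area elements must resolve
    element_target: dict[str, str] = {}  # config element_id -> map_id
    for el in config.elements.values():
        base = el.name.strip().casefold()
        if base in by_base:
            element_target[el.element_id] = by_base[base]
        elif el.element_type not in (ElementType.COMPARTMENT, ElementType.TEXT_AREA):
            raise BundleLinkError(el.name.strip() or el.element_id)

    if config.interactions:
        for inter in config.interactions.values():
            for rid in inter.reactants:
                for pid in inter.products:
                    if rid in element_target and pid in element_target:
                        bundle.link_graph.append(
                            (element_target[rid], rid, element_target[pid])
                        )
    else:
        for eid, target in element_target.items():
            if target != bundle.main_map_id:
                bundle.link_graph.append((bundle.main_map_id, eid, target))

    # materialize cross-map hyperlinks on the source maps: the config element
    # itself when it exists there, else any source-map element named after
    # the target map
    target_base = {mid: base for base, mid in by_base.items()}
    for source_map, element_id, target_map in bundle.link_graph:
        source = bundle.maps[source_map]
        if element_id in source.elements:
            sources = [element_id]
        else:
            wanted = target_base[target_map]
            sources = [
                e.element_id
                for e in source.elements.values()
                if e.name.strip().casefold() == wanted
            ]
        for eid in sources:
            link = SubmapLink(eid, target_map)
            if link not in source.submap_links:
                source.submap_links.append(link)

    return bundle


def read_bundle_dir(
    path: Union[str, Path], config_name: str
) -> Bundle:
    """Read a bundle from a directory or a zip archive of map files."""
    path = Path(path)
    files: dict[str, str] = {}
    if path.is_dir():
        for f in sorted(path.iterdir()):
            if f.suffix.lower() in (".xml", ".sbgn"):
                files[f.name] = f.read_text()
    elif zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                if name.lower().endswith((".xml", ".sbgn")):
                    files[Path(name).name] = zf.read(name).decode("utf-8")
    else:
        raise UnsupportedDialect(f"{path} is neither a directory nor a zip archive")
    return read_bundle(files, config_name)
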