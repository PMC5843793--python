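import pytest

from teocde import CDERecord, builtin_templates, default_lexicon

#: The worked caDSR record: an ECG-medication date CDE whose LongName
#: carries both "Interval" and "Date" keywords.
QT_XML = b"""<?xml version="1.0" encoding="UTF-8"?>
<DataElementsList>
  <DataElement num="36405">
    <PUBLICID>4199738</PUBLICID>
    <LONGNAME>QT Interval Medication Administered Last Date</LONGNAME>
    <PREFERREDNAME>4199693v1.0:2192181v1.0</PREFERREDNAME>
    <PREFERREDDEFINITION>information related to the date QT interval medication last administered.</PREFERREDDEFINITION>
    <DATAELEMENTCONCEPT>
      <PreferredName>4199691v1.0:2233610v1.0</PreferredName>
    </DATAELEMENTCONCEPT>
  </DataElement>
</DataElementsList>
"""


@pytest.fixture(scope="session")
def qt_xml() -> bytes:
    return QT_XML


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def registry():
    return builtin_templates()


@pytest.fixture()
def qt_record() -> CDERecord:
    return CDERecord(
        num=36405,
        public_id="4199738",
        long_name="QT Interval Medication Administered Last Date",
        preferred_name="4199693v1.0:2192181v1.0",
        preferred_definition=(
            "information related to the date QT interval medication last "
            "administered."
        ),
        data_element_concept="4199691v1.0:2233610v1.0",
    )
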