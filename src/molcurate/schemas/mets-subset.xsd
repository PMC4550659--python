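<?xml version="1.0" encoding="UTF-8"?>
<!--
  Subset profile of the Library of Congress METS schema covering the
  manifest structure this toolkit emits: a dmdSec wrapping DIM descriptive
  metadata, a fileSec whose mets:file elements carry CHECKSUMTYPE /
  CHECKSUM / MIMETYPE / SIZE with an xlink-located FLocat, and a structMap.
-->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           targetNamespace="http://www.loc.gov/METS/"
           xmlns:mets="http://www.loc.gov/METS/"
           xmlns:xlink="http://www.w3.org/1999/xlink"
           xmlns:dim="http://www.dspace.org/xmlns/dspace/dim"
           elementFormDefault="qualified">

  <xs:import namespace="http://www.w3.org/1999/xlink" schemaLocation="xlink-subset.xsd"/>
  <xs:import namespace="http://www.dspace.org/xmlns/dspace/dim" schemaLocation="dim-subset.xsd"/>

  <xs:element name="mets">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="mets:dmdSec" minOccurs="0" maxOccurs="unbounded"/>
        <xs:element ref="mets:fileSec"/>
        <xs:element ref="mets:structMap"/>
      </xs:sequence>
      <xs:attribute name="OBJID" type="xs:string"/>
      <xs:attribute name="LABEL" type="xs:string"/>
      <xs:attribute name="PROFILE" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="dmdSec">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="mets:mdWrap"/>
      </xs:sequence>
      <xs:attribute name="ID" type="xs:ID" use="required"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="mdWrap">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="mets:xmlData"/>
      </xs:sequence>
      <xs:attribute name="MDTYPE" type="xs:string" use="required"/>
      <xs:attribute name="OTHERMDTYPE" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="xmlData">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="dim:dim"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:element name="fileSec">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="mets:fileGrp" maxOccurs="unbounded"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:element name="fileGrp">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="mets:file" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="USE" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="file">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="mets:FLocat" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="ID" type="xs:ID" use="required"/>
      <xs:attribute name="GROUPID" type="xs:string"/>
      <xs:attribute name="MIMETYPE" type="xs:string" use="required"/>
      <xs:attribute name="SIZE" type="xs:nonNegativeInteger" use="required"/>
      <xs:attribute name="CHECKSUM" type="xs:string" use="required"/>
      <xs:attribute name="CHECKSUMTYPE" use="required">
        <xs:simpleType>
          <xs:restriction base="xs:string">
            <xs:enumeration value="MD5"/>
            <xs:enumeration value="SHA-1"/>
            <xs:enumeration value="SHA-256"/>
            <xs:enumeration value="SHA-512"/>
          </xs:restriction>
        </xs:simpleType>
      </xs:attribute>
    </xs:complexType>
  </xs:element>

  <xs:element name="FLocat">
    <xs:complexType>
      <xs:attribute name="LOCTYPE" type="xs:string" use="required"/>
      <xs:attribute ref="xlink:href" use="required"/>
      <xs:attribute ref="xlink:title"/>
      <xs:attribute ref="xlink:type"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="structMap">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="mets:div" maxOccurs="unbounded"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:element name="div">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="mets:fptr" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="DMDID" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="fptr">
    <xs:complexType>
      <xs:attribute name="FILEID" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
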