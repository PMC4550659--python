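<?xml version="1.0" encoding="UTF-8"?>
<!--
  Subset profile of CML 2.4 covering the elements this toolkit reads and
  writes: molecule, atomArray/atom, bondArray/bond, the legacy identifier
  element with basic/charge children, and a metadataList.  Full CML is out
  of scope; this profile is the documented validation target.
-->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           targetNamespace="http://www.xml-cml.org/schema"
           xmlns:cml="http://www.xml-cml.org/schema"
           elementFormDefault="qualified">

  <xs:element name="cml">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="cml:molecule" maxOccurs="unbounded"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:element name="molecule">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="cml:identifier" minOccurs="0"/>
        <xs:element ref="cml:atomArray"/>
        <xs:element ref="cml:bondArray" minOccurs="0"/>
        <xs:element ref="cml:metadataList" minOccurs="0"/>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string"/>
      <xs:attribute name="name" type="xs:string"/>
      <xs:attribute name="formalCharge" type="xs:integer"/>
      <xs:attribute name="provenance">
        <xs:simpleType>
          <xs:restriction base="xs:string">
            <xs:enumeration value="NCI"/>
            <xs:enumeration value="PM5"/>
            <xs:enumeration value="PM7"/>
          </xs:restriction>
        </xs:simpleType>
      </xs:attribute>
    </xs:complexType>
  </xs:element>

  <xs:element name="identifier">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="basic" type="xs:string" minOccurs="0"/>
        <xs:element name="charge" type="xs:string" minOccurs="0"/>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string"/>
      <xs:attribute name="tautomeric" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="atomArray">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="cml:atom" maxOccurs="unbounded"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:element name="atom">
    <xs:complexType>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="elementType" type="xs:string" use="required"/>
      <xs:attribute name="x3" type="xs:double"/>
      <xs:attribute name="y3" type="xs:double"/>
      <xs:attribute name="z3" type="xs:double"/>
      <xs:attribute name="isotopeNumber" type="xs:positiveInteger"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="bondArray">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="cml:bond" maxOccurs="unbounded"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:element name="bond">
    <xs:complexType>
      <xs:attribute name="atomRefs2" type="xs:string" use="required"/>
      <xs:attribute name="order" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="metadataList">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="cml:metadata" maxOccurs="unbounded"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:element name="metadata">
    <xs:complexType>
      <xs:attribute name="name" type="xs:string" use="required"/>
      <xs:attribute name="content" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
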